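"""Relative progression inference, bootstrap, Delta statistics and tests."""

import numpy as np
import pandas as pd
import pytest

from apcrisk.genotypes import (
    CL_LOH,
    CN_LOH,
    GENOTYPE_CLASSES,
    Genotype,
    genotype_mutation_probability,
)
from apcrisk.progression import (
    ProgressionModel,
    progression_delta,
    progression_weighted_mean,
    relative_progression,
    site_corrected_delta,
    weighted_expression_difference,
)

UNIFORM_M = pd.Series(1 / 18, index=list(GENOTYPE_CLASSES))


def _counts(mapping):
    return pd.Series(mapping)


class TestRelativeProgression:
    def test_frequencies_proportional_to_m_give_uniform_ptilde(self, hit_probs):
        m = genotype_mutation_probability(hit_probs)
        pt = relative_progression(m, m)
        assert np.allclose(pt, 1 / 18)

    def test_uniform_m_returns_observed_frequencies(self):
        f = pd.Series(0.0, index=list(GENOTYPE_CLASSES))
        f[(0, 1)], f[(1, 1)], f[(2, CL_LOH)] = 0.5, 0.3, 0.2
        pt = relative_progression(f, UNIFORM_M)
        assert np.allclose(pt, f)

    def test_two_class_hand_normalization(self):
        f = pd.Series(0.0, index=list(GENOTYPE_CLASSES))
        f[(0, 0)], f[(0, 1)] = 0.5, 0.5
        m = UNIFORM_M.copy()
        m[(0, 0)], m[(0, 1)] = 0.25, 0.75
        pt = relative_progression(f, m)
        # f/m = (2, 2/3) -> normalized (0.75, 0.25)
        assert pt[(0, 0)] == pytest.approx(0.75)
        assert pt[(0, 1)] == pytest.approx(0.25)
        assert pt.drop([(0, 0), (0, 1)]).sum() == 0

    def test_observed_class_with_zero_m_errors(self):
        f = pd.Series(0.0, index=list(GENOTYPE_CLASSES))
        f[(0, 0)] = 1.0
        m = UNIFORM_M.copy()
        m[(0, 0)] = 0.0
        with pytest.raises(ValueError, match="impossible"):
            relative_progression(f, m)

    def test_genotype_and_20aar_levels_consistent(self, hit_probs):
        rng = np.random.default_rng(5)
        m = genotype_mutation_probability(hit_probs)
        counts = pd.Series(
            rng.multinomial(500, m.to_numpy()), index=list(GENOTYPE_CLASSES)
        )
        model = ProgressionModel(counts, m)
        direct = relative_progression(counts / 500, m, level="20AAR")
        fit = model.fit(B=200, seed=0)
        assert np.allclose(fit.ptilde_x, direct)
        # aggregating f and m to X first is the same computation path
        fx = model.frequencies_x
        mx = model.m_x
        ratio = (fx / mx).where(fx > 0, 0.0)
        assert np.allclose(fit.ptilde_x, ratio / ratio.sum())


class TestWeightedMean:
    def test_point_mass(self):
        p = pd.Series(0.0, index=range(7))
        p[2] = 1.0
        assert progression_weighted_mean(p) == 2.0

    def test_uniform_symmetry(self):
        assert progression_weighted_mean(pd.Series(1 / 7, index=range(7))) == pytest.approx(3.0)

    def test_two_point(self):
        p = pd.Series(0.0, index=range(7))
        p[1] = p[2] = 0.5
        assert progression_weighted_mean(p) == pytest.approx(1.5)


class TestFitAndBootstrap:
    def test_single_class_cohort_degenerate_ci(self):
        model = ProgressionModel(_counts({(1, 1): 40}), UNIFORM_M)
        res = model.fit(B=200, seed=1)
        assert res.ptilde_x[2] == 1.0
        assert res.conf_int_x.loc[2, "lower"] == res.conf_int_x.loc[2, "upper"] == 1.0

    def test_ci_contains_point_estimate(self, hit_probs):
        rng = np.random.default_rng(9)
        m = genotype_mutation_probability(hit_probs)
        counts = pd.Series(
            rng.multinomial(800, m.to_numpy()), index=list(GENOTYPE_CLASSES)
        )
        res = ProgressionModel(counts, m).fit(B=500, seed=2)
        ok = (res.conf_int_x["lower"] <= res.ptilde_x + 1e-12) & (
            res.ptilde_x <= res.conf_int_x["upper"] + 1e-12
        )
        assert ok.all()

    def test_summary_mentions_key_quantities(self):
        model = ProgressionModel(_counts({(1, 1): 10, (0, 0): 10}), UNIFORM_M)
        text = model.fit(B=200, seed=0).summary()
        assert "weighted mean" in text and "tumours: 20" in text

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ProgressionModel(_counts({}), UNIFORM_M)

    def test_plot_returns_errorbar_axes(self):
        import matplotlib

        matplotlib.use("Agg")
        model = ProgressionModel(_counts({(1, 1): 10, (0, 2): 10}), UNIFORM_M)
        ax = model.fit(B=200, seed=0).plot()
        assert ax.get_xlabel().startswith("total retained")


class TestHypothesisTests:
    def test_uniform_risk_extreme_cohort_attains_floor(self):
        model = ProgressionModel(_counts({(1, 1): 500}), UNIFORM_M)
        res = model.uniform_risk_test(K=500, seed=3)
        assert res.pvalue == pytest.approx(1 / 501)

    def test_uniform_risk_null_cohort_not_rejected(self, hit_probs):
        m = genotype_mutation_probability(hit_probs)
        rng = np.random.default_rng(11)
        counts = pd.Series(
            rng.multinomial(1000, m.to_numpy()), index=list(GENOTYPE_CLASSES)
        )
        res = ProgressionModel(counts, m).uniform_risk_test(K=500, seed=4)
        assert res.pvalue > 0.05

    def test_mode_test_single_class_at_zero(self):
        model = ProgressionModel(_counts({(0, 0): 60}), UNIFORM_M)
        res = model.max_loss_mode_test(B=200, seed=5)
        assert res.mode == 0 and not res.reject_maximal_loss

    def test_mode_test_detects_planted_optimum(self, hit_probs):
        from apcrisk.simulate import default_progression_x, progression_by_genotype

        m = genotype_mutation_probability(hit_probs)
        p = progression_by_genotype(default_progression_x())
        w = m * p
        rng = np.random.default_rng(13)
        counts = pd.Series(
            rng.multinomial(1000, (w / w.sum()).to_numpy()),
            index=list(GENOTYPE_CLASSES),
        )
        res = ProgressionModel(counts, m).max_loss_mode_test(B=500, seed=6)
        assert res.mode == 2
        assert res.reject_maximal_loss


class TestDelta:
    def test_identical_groups_give_zero_delta(self):
        counts = _counts({(0, 1): 30, (1, 1): 20, (2, CL_LOH): 10})
        a = ProgressionModel(counts, UNIFORM_M)
        b = ProgressionModel(counts, UNIFORM_M)
        res = progression_delta(a, b, n_perm=199, B=200, seed=7)
        assert res.delta == pytest.approx(0.0)
        assert res.pvalue == pytest.approx(1.0)

    def test_sign_antisymmetry(self):
        a = ProgressionModel(_counts({(0, 1): 30, (1, 2): 30}), UNIFORM_M)
        b = ProgressionModel(_counts({(0, 0): 30, (0, 1): 30}), UNIFORM_M)
        ab = progression_delta(a, b, n_perm=99, B=200, seed=8)
        ba = progression_delta(b, a, n_perm=99, B=200, seed=8)
        assert ab.delta == pytest.approx(-ba.delta)

    def test_tiny_group_rejected(self):
        a = ProgressionModel(_counts({(0, 1): 1}), UNIFORM_M)
        b = ProgressionModel(_counts({(0, 0): 30}), UNIFORM_M)
        with pytest.raises(ValueError, match="at least 2"):
            progression_delta(a, b)


class TestSiteCorrectedDelta:
    def test_weighted_average_arithmetic(self):
        # stratum P: mutants at X=3, wild type at X=2 -> delta +1
        # stratum D: both at X=2 -> delta 0; mutant weights 0.6 / 0.4
        mut = {
            "P": ProgressionModel(_counts({(1, 2): 60}), UNIFORM_M),
            "D": ProgressionModel(_counts({(0, 2): 40}), UNIFORM_M),
        }
        wt = {
            "P": ProgressionModel(_counts({(0, 2): 50}), UNIFORM_M),
            "D": ProgressionModel(_counts({(0, 2): 50}), UNIFORM_M),
        }
        res = site_corrected_delta(mut, wt, B=200, seed=9)
        assert res.delta == pytest.approx(0.6)

    def test_zero_shift_everywhere(self):
        g = ProgressionModel(_counts({(0, 2): 20}), UNIFORM_M)
        res = site_corrected_delta({"P": g, "D": g}, {"P": g, "D": g}, B=200, seed=10)
        assert res.delta == pytest.approx(0.0)

    def test_missing_stratum_errors(self):
        g = ProgressionModel(_counts({(0, 2): 20}), UNIFORM_M)
        with pytest.raises(ValueError, match="site correction not possible"):
            site_corrected_delta({"P": g, "D": g}, {"P": g})


class TestWeightedExpressionDifference:
    def test_identical_groups_zero(self):
        expr = [1.0, 1.0, 2.0, 2.0]
        driver = [True, False, True, False]
        x = [1, 1, 2, 2]
        assert weighted_expression_difference(expr, driver, x) == pytest.approx(0.0)

    def test_constant_offset_recovered(self):
        expr = [3.0, 1.0, 5.0, 3.0, 7.0, 5.0]
        driver = [True, False, True, False, True, False]
        x = [0, 0, 1, 1, 2, 2]
        assert weighted_expression_difference(expr, driver, x) == pytest.approx(2.0)

    def test_two_stratum_weights(self):
        # strata diffs +2 (3 driver samples) and -1 (1 driver sample)
        expr = [4.0, 4.0, 4.0, 2.0, 1.0, 2.0]
        driver = [True, True, True, False, True, False]
        x = [1, 1, 1, 1, 2, 2]
        assert weighted_expression_difference(expr, driver, x) == pytest.approx(
            0.75 * 2.0 + 0.25 * (-1.0)
        )

    def test_no_shared_stratum_errors(self):
        with pytest.raises(ValueError, match="shared"):
            weighted_expression_difference([1.0, 2.0], [True, False], [1, 2])
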