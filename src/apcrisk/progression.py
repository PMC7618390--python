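"""Relative progression-probability inference for biallelic APC genotypes.

The central quantity is the mutation-corrected relative progression
probability: with ``f`` the observed cohort frequency of a genotype class and
``m`` its probability under mutational processes alone,

    p~ = (f / m) / sum_classes (f / m)

estimated at the genotype level (18 classes) and at the level of the total
number ``X`` of retained 20AARs (0..6), where both ``f`` and ``m`` are summed
over the classes mapping to each ``X`` before taking the ratio.  The
unobservable absolute scale (the constant relating cancer frequencies to
progression probabilities) cancels in the ratio and is never estimated.

The modelling interface follows the Model/Results convention:
:class:`ProgressionModel` holds cohort counts and the neutral genotype
distribution; :meth:`ProgressionModel.fit` returns a
:class:`ProgressionResults` carrying point estimates, percentile bootstrap
confidence intervals, the progression-weighted mean 20AAR number, the
cohort-simulation test of the "uniform risk" null and the bootstrap mode test
of the "maximal loss implies maximal risk" null.  Group comparisons (the
Delta statistic with its permutation test and the anatomic-site-corrected
variant) are module-level functions over fitted or unfitted models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genotypes import (
    GENOTYPE_CLASSES,
    X_AGGREGATION,
    X_LEVELS,
    X_OF_CLASS,
    Genotype,
)

_N_CLASSES = len(GENOTYPE_CLASSES)


def _as_count_vector(counts: pd.Series | Mapping) -> np.ndarray:
    s = pd.Series(counts, dtype=float).reindex(list(GENOTYPE_CLASSES)).fillna(0.0)
    if (s < 0).any():
        raise ValueError("counts must be nonnegative")
    return s.to_numpy()


def _ptilde_rows(counts: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Row-wise p~ = (c/m) / sum(c/m); rows with all-zero counts give zeros."""
    counts = np.atleast_2d(counts).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(counts > 0, counts / m, 0.0)
    totals = r.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return r / totals


def _weighted_mean_rows(ptilde_x: np.ndarray) -> np.ndarray:
    return np.atleast_2d(ptilde_x) @ X_LEVELS.astype(float)


def relative_progression(
    f: pd.Series | Mapping, m: pd.Series | Mapping, level: str = "genotype"
) -> pd.Series:
    """Plug-in relative progression probabilities p~ ∝ f/m, normalized.

    ``level="genotype"`` operates over the 18 genotype classes;
    ``level="20AAR"`` first aggregates both ``f`` and ``m`` over the classes
    retaining each total 20AAR number.  Classes with ``f = 0`` get
    ``p~ = 0``; ``f > 0`` where ``m = 0`` is an error (a genotype that the
    mutation model declares impossible).
    """
    fv = pd.Series(f, dtype=float).reindex(list(GENOTYPE_CLASSES)).fillna(0.0)
    mv = pd.Series(m, dtype=float).reindex(list(GENOTYPE_CLASSES))
    if mv.isna().any() or (mv < 0).any():
        raise ValueError("m must be defined and nonnegative on all genotype classes")
    if ((fv > 0) & (mv == 0)).any():
        bad = fv.index[(fv > 0) & (mv == 0)].tolist()
        raise ValueError(f"observed genotypes impossible under the mutation model: {bad}")
    if level == "genotype":
        out = _ptilde_rows(fv.to_numpy(), np.where(mv > 0, mv, 1.0))[0]
        return pd.Series(out, index=list(GENOTYPE_CLASSES))
    if level in ("20AAR", "x", "X"):
        fx = fv.to_numpy() @ X_AGGREGATION
        mx = mv.to_numpy() @ X_AGGREGATION
        out = _ptilde_rows(fx, np.where(mx > 0, mx, 1.0))[0]
        return pd.Series(out, index=X_LEVELS)
    raise ValueError(f"unknown level {level!r}")


def progression_weighted_mean(ptilde_x: pd.Series | np.ndarray) -> float:
    """Mean retained-20AAR number weighted by relative progression probability."""
    p = np.asarray(pd.Series(ptilde_x).reindex(X_LEVELS).fillna(0.0), dtype=float)
    if not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise ValueError("p~_X must be normalized")
    return float(p @ X_LEVELS)


@dataclass
class UniformRiskTest:
    statistic: float
    pvalue: float
    n_sim: int
    level: str
    seed: Optional[int]


@dataclass
class ModeTest:
    mode: int
    ci: tuple[int, int]
    reject_maximal_loss: bool
    n_boot: int
    tie_count: int
    seed: Optional[int]


@dataclass
class DeltaResult:
    """Difference in progression-weighted mean 20AARs between two groups."""

    weighted_mean_a: float
    weighted_mean_b: float
    delta: float
    pvalue: Optional[float] = None
    ci: Optional[tuple[float, float]] = None
    n_perm: Optional[int] = None
    n_boot: Optional[int] = None
    seed: Optional[int] = None


class ProgressionModel:
    """Cohort genotype counts plus the neutral genotype distribution.

    Parameters
    ----------
    counts
        Tumour counts per genotype class, indexed by ``(M, N)`` tuples.
        Missing classes count zero.
    m
        Neutral genotype-class probabilities (e.g. from
        :func:`apcrisk.genotypes.genotype_mutation_probability`).  Must be
        positive wherever ``counts`` is positive.
    """

    def __init__(self, counts: pd.Series | Mapping, m: pd.Series | Mapping):
        self.counts = pd.Series(
            _as_count_vector(counts), index=list(GENOTYPE_CLASSES)
        )
        m = pd.Series(m, dtype=float).reindex(list(GENOTYPE_CLASSES))
        if m.isna().any() or (m < 0).any():
            raise ValueError("m must be defined and nonnegative on all genotype classes")
        if ((self.counts > 0) & (m == 0)).any():
            bad = self.counts.index[(self.counts > 0) & (m == 0)].tolist()
            raise ValueError(
                f"observed genotypes impossible under the mutation model: {bad}"
            )
        self.m = m / m.sum()
        self.nobs = int(round(self.counts.sum()))
        if self.nobs == 0:
            raise ValueError("cohort is empty")

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_genotypes(
        cls, genotypes: Iterable[Genotype | tuple], m: pd.Series | Mapping
    ) -> "ProgressionModel":
        keys = [g.as_tuple() if isinstance(g, Genotype) else tuple(g) for g in genotypes]
        counts = pd.Series(keys).value_counts()
        return cls(counts, m)

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, m: pd.Series | Mapping
    ) -> "ProgressionModel":
        """Build from a genotype table with ``M`` and ``N`` columns.

        ``N`` may hold integers or the strings ``"-"``/``"x2"``; rows with a
        missing genotype (excluded tumours) are dropped.
        """
        df = data.dropna(subset=["M", "N"])

        def _n(v):
            return v if isinstance(v, str) and not v.lstrip("-").isdigit() else int(v)

        genos = [Genotype(int(r.M), _n(r.N)) for r in df.itertuples()]
        return cls.from_genotypes(genos, m)

    # -- derived quantities ------------------------------------------------
    @property
    def frequencies(self) -> pd.Series:
        """Observed genotype-class frequencies f_(M,N)."""
        return self.counts / self.nobs

    @property
    def frequencies_x(self) -> pd.Series:
        fx = self.counts.to_numpy() @ X_AGGREGATION / self.nobs
        return pd.Series(fx, index=X_LEVELS)

    @property
    def m_x(self) -> pd.Series:
        return pd.Series(self.m.to_numpy() @ X_AGGREGATION, index=X_LEVELS)

    def _m_arrays(self):
        mg = np.where(self.m.to_numpy() > 0, self.m.to_numpy(), 1.0)
        mx_raw = self.m.to_numpy() @ X_AGGREGATION
        mx = np.where(mx_raw > 0, mx_raw, 1.0)
        return mg, mx

    # -- fitting -----------------------------------------------------------
    def fit(
        self, B: int = 10_000, alpha: float = 0.05, seed: Optional[int] = None
    ) -> "ProgressionResults":
        """Estimate p~ with percentile bootstrap CIs (tumour-level resampling)."""
        if B < 100:
            raise ValueError("B must be at least 100")
        rng = np.random.default_rng(seed)
        mg, mx = self._m_arrays()
        counts = self.counts.to_numpy()
        pt_g = _ptilde_rows(counts, mg)[0]
        pt_x = _ptilde_rows(counts @ X_AGGREGATION, mx)[0]

        boot_counts = rng.multinomial(self.nobs, counts / self.nobs, size=B)
        boot_g = _ptilde_rows(boot_counts, mg)
        boot_x = _ptilde_rows(boot_counts @ X_AGGREGATION, mx)
        lo, hi = 100 * alpha / 2, 100 * (1 - alpha / 2)
        ci_g = np.percentile(boot_g, [lo, hi], axis=0).T
        ci_x = np.percentile(boot_x, [lo, hi], axis=0).T
        wm = _weighted_mean_rows(pt_x)[0]
        wm_boot = _weighted_mean_rows(boot_x)
        wm_ci = tuple(np.percentile(wm_boot, [lo, hi]))
        return ProgressionResults(
            model=self,
            ptilde=pd.Series(pt_g, index=list(GENOTYPE_CLASSES)),
            ptilde_x=pd.Series(pt_x, index=X_LEVELS),
            conf_int_genotype=pd.DataFrame(
                ci_g, index=list(GENOTYPE_CLASSES), columns=["lower", "upper"]
            ),
            conf_int_x=pd.DataFrame(ci_x, index=X_LEVELS, columns=["lower", "upper"]),
            weighted_mean=float(wm),
            weighted_mean_ci=(float(wm_ci[0]), float(wm_ci[1])),
            B=B,
            alpha=alpha,
            seed=seed,
        )

    # -- hypothesis tests --------------------------------------------------
    def uniform_risk_test(
        self, K: int = 10_000, seed: Optional[int] = None, level: str = "20AAR"
    ) -> UniformRiskTest:
        """Simulation test of the "uniform risk" null.

        Cohorts of the observed size are drawn from the neutral genotype
        distribution ``m``; the statistic is the spread (max - min) of the
        inferred p~ over the index set.  The p-value is the fraction of
        simulated cohorts with a spread at least as large as observed, with
        +1 continuity correction.
        """
        if K < 100:
            raise ValueError("K must be at least 100")
        rng = np.random.default_rng(seed)
        mg, mx = self._m_arrays()
        counts = self.counts.to_numpy()
        sims = rng.multinomial(self.nobs, self.m.to_numpy(), size=K)
        if level in ("20AAR", "x", "X"):
            obs = _ptilde_rows(counts @ X_AGGREGATION, mx)[0]
            sim_pt = _ptilde_rows(sims @ X_AGGREGATION, mx)
        elif level == "genotype":
            obs = _ptilde_rows(counts, mg)[0]
            sim_pt = _ptilde_rows(sims, mg)
        else:
            raise ValueError(f"unknown level {level!r}")
        stat = float(obs.max() - obs.min())
        sim_stat = sim_pt.max(axis=1) - sim_pt.min(axis=1)
        p = (np.count_nonzero(sim_stat >= stat) + 1) / (K + 1)
        return UniformRiskTest(stat, float(p), K, level, seed)

    def max_loss_mode_test(
        self, B: int = 10_000, alpha: float = 0.05, seed: Optional[int] = None
    ) -> ModeTest:
        """Bootstrap mode test of the "maximal loss implies maximal risk" null.

        Bootstraps the cohort, recomputes p~_X per replicate and takes the
        arg-max over X (ties broken toward smaller X, which is conservative
        for this test); the null is rejected iff X = 0 falls outside the
        central 95% interval of the bootstrap mode distribution.  Meaningful
        after the uniform-risk null has been rejected.
        """
        if B < 100:
            raise ValueError("B must be at least 100")
        rng = np.random.default_rng(seed)
        _, mx = self._m_arrays()
        counts = self.counts.to_numpy()
        boot = rng.multinomial(self.nobs, counts / self.nobs, size=B)
        pt_x = _ptilde_rows(boot @ X_AGGREGATION, mx)
        modes = pt_x.argmax(axis=1)  # argmax returns the first (smallest X) on ties
        ties = np.count_nonzero(
            (pt_x == pt_x.max(axis=1, keepdims=True)).sum(axis=1) > 1
        )
        lo = int(np.quantile(modes, alpha / 2, method="inverted_cdf"))
        hi = int(np.quantile(modes, 1 - alpha / 2, method="higher"))
        obs_mode = int(_ptilde_rows(counts @ X_AGGREGATION, mx)[0].argmax())
        return ModeTest(
            mode=obs_mode,
            ci=(lo, hi),
            reject_maximal_loss=not (lo <= 0 <= hi),
            n_boot=B,
            tie_count=int(ties),
            seed=seed,
        )


@dataclass
class ProgressionResults:
    """Estimates, uncertainties and diagnostics from :meth:`ProgressionModel.fit`."""

    model: ProgressionModel
    ptilde: pd.Series
    ptilde_x: pd.Series
    conf_int_genotype: pd.DataFrame
    conf_int_x: pd.DataFrame
    weighted_mean: float
    weighted_mean_ci: tuple[float, float]
    B: int
    alpha: float
    seed: Optional[int]

    def conf_int(self, level: str = "20AAR") -> pd.DataFrame:
        return self.conf_int_x if level in ("20AAR", "x", "X") else self.conf_int_genotype

    def uniform_risk_test(self, K: int = 10_000, seed=None, level="20AAR"):
        return self.model.uniform_risk_test(K=K, seed=seed, level=level)

    def max_loss_mode_test(self, B: int = 10_000, alpha: float = 0.05, seed=None):
        return self.model.max_loss_mode_test(B=B, alpha=alpha, seed=seed)

    def summary(self) -> str:
        lines = [
            "Relative APC progression probabilities",
            "=" * 54,
            f"tumours: {self.model.nobs}    bootstrap B: {self.B}    "
            f"alpha: {self.alpha}    seed: {self.seed}",
            "",
            f"{'X':>3} {'f_X':>8} {'m_X':>8} {'p~_X':>8} "
            f"{'[{:g}% CI]'.format(100 * (1 - self.alpha)):>18}",
        ]
        fx = self.model.frequencies_x
        mx = self.model.m_x
        for x in X_LEVELS:
            lo, hi = self.conf_int_x.loc[x]
            lines.append(
                f"{x:>3} {fx[x]:>8.4f} {mx[x]:>8.4f} {self.ptilde_x[x]:>8.4f} "
                f"  [{lo:>7.4f}, {hi:>7.4f}]"
            )
        lines += [
            "",
            f"progression-weighted mean 20AARs: {self.weighted_mean:.3f}  "
            f"CI [{self.weighted_mean_ci[0]:.3f}, {self.weighted_mean_ci[1]:.3f}]",
        ]
        return "\n".join(lines)

    def plot(self, ax=None, **kwargs):
        """Errorbar plot of p~_X against the retained-20AAR number."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        err = np.abs(
            self.conf_int_x.to_numpy().T - self.ptilde_x.to_numpy()[None, :]
        )
        ax.errorbar(
            X_LEVELS, self.ptilde_x, yerr=err, fmt="o", capsize=3, **kwargs
        )
        ax.set_xlabel("total retained 20AARs (X)")
        ax.set_ylabel(r"relative progression probability $\tilde{p}_X$")
        return ax


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def _wm_from_counts(counts: np.ndarray, m: pd.Series) -> np.ndarray:
    mx_raw = m.to_numpy() @ X_AGGREGATION
    mx = np.where(mx_raw > 0, mx_raw, 1.0)
    return _weighted_mean_rows(_ptilde_rows(np.atleast_2d(counts) @ X_AGGREGATION, mx))


def progression_delta(
    model_a: ProgressionModel,
    model_b: ProgressionModel,
    n_perm: int = 999,
    B: int = 2_000,
    alpha: float = 0.05,
    seed: Optional[int] = None,
) -> DeltaResult:
    """Delta_A-B with a two-sided permutation test and a bootstrap CI.

    The permutation test shuffles group labels across the pooled tumours
    (preserving group sizes; implemented as multivariate-hypergeometric
    splits of the pooled genotype counts), evaluating each permuted group
    with its own label's mutation model.  The CI bootstraps each group
    independently.
    """
    if model_a.nobs < 2 or model_b.nobs < 2:
        raise ValueError("each group needs at least 2 tumours")
    rng = np.random.default_rng(seed)
    ca = model_a.counts.to_numpy().astype(np.int64)
    cb = model_b.counts.to_numpy().astype(np.int64)
    wm_a = float(_wm_from_counts(ca, model_a.m)[0])
    wm_b = float(_wm_from_counts(cb, model_b.m)[0])
    delta = wm_a - wm_b

    pooled = ca + cb
    perm_a = rng.multivariate_hypergeometric(pooled, model_a.nobs, size=n_perm)
    perm_b = pooled[None, :] - perm_a
    deltas = _wm_from_counts(perm_a, model_a.m) - _wm_from_counts(perm_b, model_b.m)
    pvalue = (np.count_nonzero(np.abs(deltas) >= abs(delta)) + 1) / (n_perm + 1)

    boot_a = rng.multinomial(model_a.nobs, ca / ca.sum(), size=B)
    boot_b = rng.multinomial(model_b.nobs, cb / cb.sum(), size=B)
    boot_delta = _wm_from_counts(boot_a, model_a.m) - _wm_from_counts(boot_b, model_b.m)
    lo, hi = np.percentile(boot_delta, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return DeltaResult(
        weighted_mean_a=wm_a,
        weighted_mean_b=wm_b,
        delta=float(delta),
        pvalue=float(pvalue),
        ci=(float(lo), float(hi)),
        n_perm=n_perm,
        n_boot=B,
        seed=seed,
    )


def site_corrected_delta(
    mutant: Mapping[str, ProgressionModel],
    wildtype: Mapping[str, ProgressionModel],
    B: int = 2_000,
    alpha: float = 0.05,
    seed: Optional[int] = None,
) -> DeltaResult:
    """Anatomic-site-corrected Delta_mutant-WT.

    Computes the per-site difference in progression-weighted mean 20AARs and
    averages it with weights equal to the fraction of mutant tumours at each
    site, removing site-specific mutational and selective biases.  A positive
    value indicates the mutated gene upregulates WNT (tumours tolerate more
    retained 20AARs).
    """
    sites = sorted(mutant)
    if sorted(wildtype) != sites or not sites:
        raise ValueError(
            "site correction not possible: every site stratum must be present "
            "in both the mutant and wild-type groups"
        )
    rng = np.random.default_rng(seed)
    n_mut = np.array([mutant[s].nobs for s in sites], dtype=float)
    w = n_mut / n_mut.sum()
    deltas, boot = [], np.zeros(B)
    wm_a = wm_b = 0.0
    for wt, s in zip(w, sites):
        ma, mb = mutant[s], wildtype[s]
        da = float(_wm_from_counts(ma.counts.to_numpy(), ma.m)[0])
        db = float(_wm_from_counts(mb.counts.to_numpy(), mb.m)[0])
        deltas.append(da - db)
        wm_a += wt * da
        wm_b += wt * db
        boot_a = rng.multinomial(ma.nobs, ma.counts.to_numpy() / ma.nobs, size=B)
        boot_b = rng.multinomial(mb.nobs, mb.counts.to_numpy() / mb.nobs, size=B)
        boot += wt * (_wm_from_counts(boot_a, ma.m) - _wm_from_counts(boot_b, mb.m))
    delta = float(np.dot(w, deltas))
    lo, hi = np.percentile(boot, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return DeltaResult(
        weighted_mean_a=float(wm_a),
        weighted_mean_b=float(wm_b),
        delta=delta,
        ci=(float(lo), float(hi)),
        n_boot=B,
        seed=seed,
    )


def weighted_expression_difference(
    expression: Sequence[float],
    has_extra_driver: Sequence[bool],
    x: Sequence[int],
) -> float:
    """Sample-weighted expression difference between driver and APC-only tumours.

    For each retained-20AAR stratum ``X`` present in both groups, the
    difference in mean expression (driver minus APC-only) is computed and
    averaged with weights proportional to the number of driver-group samples
    at that ``X``.
    """
    df = pd.DataFrame(
        {
            "expr": np.asarray(expression, dtype=float),
            "driver": np.asarray(has_extra_driver, dtype=bool),
            "x": np.asarray(x),
        }
    )
    means = df.groupby(["x", "driver"])["expr"].mean().unstack("driver")
    if True not in means.columns or False not in means.columns:
        raise ValueError("both groups must be represented")
    shared = means.dropna().index
    if len(shared) == 0:
        raise ValueError("no retained-20AAR stratum is shared by both groups")
    counts = (
        df[df["driver"]].groupby("x")["expr"].size().reindex(shared).astype(float)
    )
    w = counts / counts.sum()
    diff = means.loc[shared, True] - means.loc[shared, False]
    return float((w * diff).sum())
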