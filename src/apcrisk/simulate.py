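"""Synthetic inputs with known ground truth.

Generates everything the pipeline consumes -- coding sequences with plantable
homopolymer runs, concentrated or uniform signature fixtures, sporadic
cohorts drawn from known mutation and progression probabilities, and FAP
cohorts -- so that every stage is testable end to end without external data.

The generator's defaults are the study conditions this package models:

* cohort size ``n = 1000`` (the microsatellite-stable analysis-cohort scale);
* regional truncation weights ``(0.849, 0.050, 0.051, 0.050)`` anchored to
  the R0 share implied by the printed regional and total truncation rates,
  with the remainder split near-evenly across R1-R3 (the short R3 is boosted
  by homopolymer-deletion activity);
* LOH frequency ratios ``f_(0,-)/f_(0,0) = 1.86`` and
  ``f_(0,x2)/f_(0,0) = 1.43``, i.e. hit-rate ratios ``(0.93, 1.43)``;
* a planted progression curve over retained 20AARs peaking at ``X = 2`` with
  a 50-fold range above complete loss and a monotone decay to ``X = 6``:
  ``p_X ∝ (1, 25, 50, 35, 20, 10, 5)``;
* proximal:distal group sizes 313:574 for anatomic-site comparisons.

Cohort genotypes are drawn multinomially with probability proportional to
``m_(M,N) p_(M,N)`` and then materialized as concrete mutation rows (codons
uniform within their region, class drawn from the stop-gain/frameshift mix)
plus a copy-number state realizing the intended ploidy class and metadata.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cds import BASES, DEFAULT_REGIONS, STOP_CODONS, CdsContext
from .genotypes import (
    CL_LOH,
    CN_LOH,
    GENOTYPE_CLASSES,
    HIT_TYPES,
    X_OF_CLASS,
    genotype_mutation_probability,
    hit_probabilities,
)
from .signatures import TruncationMix

DEFAULT_REGIONAL_M = (0.849, 0.050, 0.051, 0.050)
DEFAULT_LOH_RATIOS = (0.93, 1.43)  # (m_-/m_0, m_x2/m_0)
DEFAULT_TRUE_P_X = (1.0, 25.0, 50.0, 35.0, 20.0, 10.0, 5.0)
DEFAULT_SITE_SIZES = {"proximal": 313, "distal": 574}


def default_hit_probabilities() -> pd.Series:
    """The six hit-type probabilities under the default study conditions."""
    return hit_probabilities(DEFAULT_REGIONAL_M, *DEFAULT_LOH_RATIOS)


def default_progression_x() -> pd.Series:
    """Planted relative progression curve over retained 20AARs (sums to 1)."""
    p = np.asarray(DEFAULT_TRUE_P_X, dtype=float)
    return pd.Series(p / p.sum(), index=np.arange(7))


def progression_by_genotype(p_x: pd.Series | Sequence[float]) -> pd.Series:
    """Expand a retained-20AAR progression curve to the 18 genotype classes."""
    p = np.asarray(pd.Series(p_x).reindex(np.arange(7)), dtype=float)
    if np.isnan(p).any() or (p < 0).any():
        raise ValueError("p_x must be nonnegative and defined on X = 0..6")
    return pd.Series(p[X_OF_CLASS], index=list(GENOTYPE_CLASSES))


def tilt_progression(p_x: pd.Series | Sequence[float], delta: float) -> pd.Series:
    """Exponentially tilt a progression curve to shift its weighted mean.

    Returns ``q_x ∝ p_x * exp(theta x)`` with ``theta`` solved so that the
    progression-weighted mean increases by exactly ``delta``; used to plant a
    known between-group difference.
    """
    p = np.asarray(pd.Series(p_x).reindex(np.arange(7)), dtype=float)
    p = p / p.sum()
    x = np.arange(7.0)
    wm0 = p @ x
    target = wm0 + delta
    if not 0 < target < 6:
        raise ValueError(f"target weighted mean {target} outside (0, 6)")

    def gap(theta):
        q = p * np.exp(theta * x)
        q /= q.sum()
        return q @ x - target

    theta = brentq(gap, -50.0, 50.0)
    q = p * np.exp(theta * x)
    return pd.Series(q / q.sum(), index=np.arange(7))


def synthetic_regions(n_codons: int) -> dict[str, tuple[int, int]]:
    """APC-proportioned region layout scaled to a smaller CDS.

    R0 covers ~80% of the window, R1-R3 the rest, and ~6% of codons stay
    downstream of the cutoff.
    """
    cutoff = max(int(round(n_codons * 0.94)), 8)
    cutoff = min(cutoff, n_codons)
    b0 = max(int(round(cutoff * 0.80)), 1)
    rest = cutoff - b0
    if rest < 3:
        raise ValueError(f"CDS of {n_codons} codons too short for four regions")
    b1 = b0 + rest // 3
    b2 = b1 + rest // 3
    return {
        "R0": (1, b0),
        "R1": (b0 + 1, b1),
        "R2": (b1 + 1, b2),
        "R3": (b2 + 1, cutoff),
    }


def generate_cds(
    n_codons: int,
    seed: int,
    gc: float = 0.42,
    homopolymer_runs: Sequence[tuple[str, int, int]] = (),
    regions: Optional[Mapping[str, tuple[int, int]]] = None,
) -> CdsContext:
    """Random stop-free CDS with homopolymer runs planted at exact positions.

    ``homopolymer_runs`` are ``(base, length, codon)`` triples; the run is
    written starting at the first nucleotide of the given codon.  Raises if
    runs overlap or if planting creates an in-frame stop codon.
    """
    if n_codons < 2:
        raise ValueError("need at least 2 codons")
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng([seed, 0])
    codons = [
        "".join(t)
        for t in itertools.product(BASES, repeat=3)
        if "".join(t) not in STOP_CODONS
    ]
    weights = np.array(
        [np.prod([gc / 2 if b in "GC" else (1 - gc) / 2 for b in c]) for c in codons]
    )
    weights /= weights.sum()
    seq = list("".join(rng.choice(codons, size=n_codons, p=weights)))

    occupied: set[int] = set()
    for base, length, codon in homopolymer_runs:
        if base not in BASES:
            raise ValueError(f"run base {base!r} invalid")
        start = 3 * (codon - 1)
        if codon < 1 or start + length > len(seq):
            raise ValueError(f"run of {length} {base} at codon {codon} outside the CDS")
        span = set(range(start, start + length))
        if span & occupied:
            raise ValueError(f"run at codon {codon} overlaps a previously planted run")
        occupied |= span
        for i in span:
            seq[i] = base
    sequence = "".join(seq)
    for i in range(0, len(sequence), 3):
        if sequence[i : i + 3] in STOP_CODONS:
            raise ValueError(
                f"planting created an in-frame stop at codon {i // 3 + 1}"
            )
    return CdsContext(sequence=sequence, regions=dict(regions or synthetic_regions(n_codons)))


def _region_bounds(regions: Mapping[str, tuple[int, int]]) -> list[tuple[int, int]]:
    return [regions[f"R{j}"] for j in range(4)]


def generate_cohort(
    n: int = 1000,
    seed: int = 0,
    m_hit: Optional[pd.Series] = None,
    p_x: Optional[pd.Series | Sequence[float]] = None,
    mix: Optional[TruncationMix] = None,
    regions: Optional[Mapping[str, tuple[int, int]]] = None,
    site_fractions: Optional[Mapping[str, float]] = None,
) -> tuple[pd.DataFrame, dict]:
    """Sporadic cohort drawn from known mutation and progression probabilities.

    Returns a tidy mutation table (one row per mutation, with sample-level
    copy-number and metadata columns repeated) plus a ground-truth record of
    the generating parameters and expected genotype frequencies.
    """
    if n <= 0:
        raise ValueError("cohort size must be positive")
    m_hit = default_hit_probabilities() if m_hit is None else pd.Series(m_hit)
    p_x = default_progression_x() if p_x is None else pd.Series(p_x, dtype=float)
    mix = mix or TruncationMix.from_stop_frameshift_ratio(15, 11)
    regions = dict(regions or DEFAULT_REGIONS)
    if site_fractions is None:
        total = sum(DEFAULT_SITE_SIZES.values())
        site_fractions = {k: v / total for k, v in DEFAULT_SITE_SIZES.items()}
    m_geno = genotype_mutation_probability(m_hit)
    p_geno = progression_by_genotype(p_x)
    w = (m_geno * p_geno).to_numpy()
    if w.sum() <= 0:
        raise ValueError("m and p give a zero-support genotype distribution")
    w = w / w.sum()

    rng = np.random.default_rng([seed, 1])
    class_counts = rng.multinomial(n, w)
    bounds = _region_bounds(regions)
    sites = list(site_fractions)
    site_p = np.array([site_fractions[s] for s in sites], dtype=float)
    site_p /= site_p.sum()

    rows = []
    sample_no = 0
    for (M, N), count in zip(GENOTYPE_CLASSES, class_counts):
        for _ in range(count):
            sample_no += 1
            sid = f"S{sample_no:05d}"
            if isinstance(N, int):
                cn_a, cn_b = 1, 1
                hit_regions = [M, N]
            elif N == CL_LOH:
                cn_a, cn_b = 1, 0
                hit_regions = [M]
            else:  # CN-LOH
                cn_a, cn_b = int(rng.choice([2, 3], p=[0.8, 0.2])), 0
                hit_regions = [M]
            meta = {
                "cn_a": cn_a,
                "cn_b": cn_b,
                "wgd": False,
                "site": sites[rng.choice(len(sites), p=site_p)],
                "msi": False,
                "pole": False,
                "is_primary": True,
                "prior_radiotherapy": False,
                "germline_apc": False,
                "lynch_syndrome": False,
                "age": int(np.clip(rng.normal(69, 11), 23, 94)),
                "sex": "M" if rng.random() < 0.594 else "F",
            }
            for j in hit_regions:
                lo, hi = bounds[j]
                rows.append(
                    {
                        "sample": sid,
                        "codon": int(rng.integers(lo, hi + 1)),
                        "mutation_class": (
                            "stop_gain"
                            if rng.random() < mix.p_stop_gain
                            else "frameshift"
                        ),
                        "clonal": True,
                        **meta,
                    }
                )
    cohort = pd.DataFrame(rows)
    truth = {
        "seed": seed,
        "n": n,
        "m_hit": {str(k): float(v) for k, v in m_hit.items()},
        "p_x": {int(k): float(v) for k, v in (p_x / p_x.sum()).items()},
        "m_genotype": {f"({M},{N})": float(v) for (M, N), v in m_geno.items()},
        "expected_f": {f"({M},{N})": float(v) for (M, N), v in zip(GENOTYPE_CLASSES, w)},
        "weighted_mean": float(
            (p_x / p_x.sum()).to_numpy() @ np.arange(len(p_x), dtype=float)
        ),
        "p_stop_gain": mix.p_stop_gain,
    }
    return cohort, truth


def generate_fap_cohort(
    germline_region: int,
    m_hit: Optional[pd.Series] = None,
    p: Optional[pd.Series] = None,
    n: int = 100,
    seed: int = 0,
    study: str = "synthetic",
) -> tuple[pd.DataFrame, dict]:
    """FAP cohort: somatic second hits drawn conditional on the germline region."""
    from .fap import fap_somatic_distribution

    if n <= 0:
        raise ValueError("cohort size must be positive")
    m_hit = default_hit_probabilities() if m_hit is None else pd.Series(m_hit)
    if p is None:
        p = progression_by_genotype(default_progression_x())
    pred = fap_somatic_distribution(germline_region, m_hit, p)
    rng = np.random.default_rng([seed, 2])
    draws = rng.choice(len(HIT_TYPES), size=n, p=pred.distribution.to_numpy())
    rows = []
    for i, d in enumerate(draws, start=1):
        somatic = HIT_TYPES[d]
        rows.append(
            {
                "study": study,
                "patient": f"P{i:04d}",
                "germline_region": germline_region,
                "somatic_type": str(somatic),
                "somatic_category": (
                    "LOH" if somatic in (CL_LOH, CN_LOH) else str(somatic)
                ),
            }
        )
    truth = {
        "seed": seed,
        "n": n,
        "germline_region": germline_region,
        "distribution": {str(k): float(v) for k, v in pred.distribution.items()},
        "merged": {str(k): float(v) for k, v in pred.merged_loh().items()},
    }
    return pd.DataFrame(rows), truth


@dataclass
class SyntheticSpec:
    """Bundled generator settings with hierarchical seeding.

    One pseudo-random stream per artifact (CDS, cohort, FAP cohort) is derived
    from the spec seed, so regenerating one artifact never perturbs another.
    """

    seed: int = 0
    n_codons: int = 120
    gc: float = 0.42
    homopolymer_runs: Sequence[tuple[str, int, int]] = ()
    cohort_n: int = 1000
    m_hit: Optional[pd.Series] = None
    p_x: Optional[pd.Series] = None
    site_fractions: Optional[Mapping[str, float]] = None

    def cds(self) -> CdsContext:
        return generate_cds(
            self.n_codons, seed=self.seed, gc=self.gc,
            homopolymer_runs=self.homopolymer_runs,
        )

    def cohort(self) -> tuple[pd.DataFrame, dict]:
        return generate_cohort(
            n=self.cohort_n, seed=self.seed, m_hit=self.m_hit, p_x=self.p_x,
            site_fractions=self.site_fractions,
        )

    def fap(self, germline_region: int, n: int = 100) -> tuple[pd.DataFrame, dict]:
        return generate_fap_cohort(
            germline_region, m_hit=self.m_hit,
            p=None if self.p_x is None else progression_by_genotype(self.p_x),
            n=n, seed=self.seed,
        )
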