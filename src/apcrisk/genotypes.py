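"""Biallelic APC genotype calculus.

A tumour's two APC hits are summarised as an unordered genotype ``(M, N)``:
``M`` is the region (0-3) of the most upstream truncating mutation and ``N``
is either the region of the second truncating mutation (``M <= N``), a
copy-loss LOH (``"-"``) or a copy-neutral LOH (``"x2"``).  The total number of
retained 20-amino-acid beta-catenin-binding repeats across both alleles is
``X = M + N`` (both truncating), ``X = M`` (CL-LOH removes the other allele)
or ``X = 2M`` (CN-LOH duplicates the mutant allele).

The module also computes the neutral genotype distribution implied by per-hit
type probabilities (two independent hits, CN-LOH second-hit-only, the
unobserved classes (-,-) and CN-LOH-first excluded) and the LOH rate ratios
estimable from the frequencies of the zero-20AAR genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .cds import DOWNSTREAM, CdsContext, region_of_codon

CL_LOH = "-"
CN_LOH = "x2"

HitType = Union[int, str]

#: The six first/second-hit types and their canonical order.
HIT_TYPES: tuple[HitType, ...] = (0, 1, 2, 3, CL_LOH, CN_LOH)

#: The 18 admissible unordered genotype classes.
GENOTYPE_CLASSES: tuple[tuple[HitType, HitType], ...] = tuple(
    (M, N) for M in range(4) for N in (*range(M, 4), CL_LOH, CN_LOH)
)


def retained_20aars(M: int, N: HitType) -> int:
    """Total 20AARs retained across both alleles for genotype (M, N)."""
    if N == CL_LOH:
        return M
    if N == CN_LOH:
        return 2 * M
    return M + N


#: X value of each genotype class, in GENOTYPE_CLASSES order.
X_OF_CLASS = np.array([retained_20aars(M, N) for M, N in GENOTYPE_CLASSES])

X_LEVELS = np.arange(7)

#: Boolean aggregation matrix (18 x 7): class -> retained-20AAR level.
X_AGGREGATION = (X_OF_CLASS[:, None] == X_LEVELS[None, :]).astype(float)


@dataclass(frozen=True)
class Genotype:
    """An unordered biallelic APC genotype label."""

    M: int
    N: HitType

    def __post_init__(self):
        if self.M not in (0, 1, 2, 3):
            raise ValueError(f"M must be a region index 0-3, got {self.M!r}")
        if isinstance(self.N, int):
            if not self.M <= self.N <= 3:
                raise ValueError(f"numeric N must satisfy M <= N <= 3, got {self!r}")
        elif self.N not in (CL_LOH, CN_LOH):
            raise ValueError(f"N must be 0-3, '-' or 'x2', got {self.N!r}")

    @property
    def X(self) -> int:
        return retained_20aars(self.M, self.N)

    def as_tuple(self) -> tuple[HitType, HitType]:
        return (self.M, self.N)

    def __str__(self):
        return f"({self.M},{self.N})"


@dataclass(frozen=True)
class TruncatingMutation:
    codon: int
    mutation_class: str  # "stop_gain" | "frameshift"
    clonal: bool = True


@dataclass
class TumorRecord:
    """One tumour: its truncating APC mutations, copy-number state and labels."""

    sample: str
    mutations: Sequence[TruncatingMutation]
    cn: tuple[int, int]  # (major, minor) allele copy number at the APC locus
    wgd: bool = False
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        a, b = self.cn
        if not (a >= b >= 0):
            raise ValueError(f"copy number must satisfy a >= b >= 0, got {self.cn}")


class UnclassifiablePloidyError(ValueError):
    """Copy-number state outside the recognised diploid/CL-LOH/CN-LOH table."""


def ploidy_at_initiation(a: int, b: int, wgd: bool) -> str:
    """Classify APC ploidy at tumour initiation from allele-specific CN.

    Whole-genome duplication is assumed to postdate APC inactivation, so under
    WGD a balanced locus still counts as diploid at initiation.
    Returns ``"diploid"``, ``"CL-LOH"`` or ``"CN-LOH"``.
    """
    if not (a >= b >= 0):
        raise ValueError(f"copy number must satisfy a >= b >= 0, got ({a}, {b})")
    if not wgd:
        if (a, b) == (1, 1):
            return "diploid"
        if (a, b) == (1, 0):
            return "CL-LOH"
        if a >= 2 and b == 0:
            return "CN-LOH"
    else:
        if a > 0 and b > 0:
            return "diploid"
        if b == 0 and 1 <= a <= 2:
            return "CL-LOH"
        if b == 0 and a > 2:
            return "CN-LOH"
    raise UnclassifiablePloidyError(
        f"copy-number state [{a},{b}] (WGD={wgd}) not classifiable at initiation"
    )


@dataclass
class TumorClassification:
    """Outcome of genotyping one tumour."""

    sample: str
    genotype: Optional[Genotype]
    exclusion_reason: Optional[str] = None
    third_hits: int = 0

    @property
    def excluded(self) -> bool:
        return self.genotype is None


_REGION_INDEX = {"R0": 0, "R1": 1, "R2": 2, "R3": 3}


def classify_tumor(rec: TumorRecord, ctx: CdsContext) -> TumorClassification:
    """Assign a biallelic genotype to a tumour, or an exclusion reason.

    Clonal truncating mutations inside the analysis window are ordered by
    codon (most upstream first); with unphased data the two most upstream
    mutations are taken as the two alleles.  Mutations downstream of the
    SAMP cutoff are ignored.
    """
    hits = []
    for mut in rec.mutations:
        if not mut.clonal:
            continue
        region = region_of_codon(mut.codon, ctx)
        if region == DOWNSTREAM:
            continue
        hits.append((mut.codon, _REGION_INDEX[region]))
    hits.sort()
    if not hits:
        return TumorClassification(
            rec.sample, None, exclusion_reason="no in-window truncating hit"
        )
    try:
        ploidy = ploidy_at_initiation(rec.cn[0], rec.cn[1], rec.wgd)
    except UnclassifiablePloidyError:
        return TumorClassification(
            rec.sample, None, exclusion_reason="unclassifiable copy-number state"
        )
    if ploidy == "diploid":
        if len(hits) < 2:
            return TumorClassification(
                rec.sample,
                None,
                exclusion_reason="diploid with a single truncating mutation",
            )
        regions = sorted((hits[0][1], hits[1][1]))
        geno = Genotype(regions[0], regions[1])
        extra = len(hits) - 2
    else:
        second = CL_LOH if ploidy == "CL-LOH" else CN_LOH
        geno = Genotype(hits[0][1], second)
        extra = len(hits) - 1
    return TumorClassification(rec.sample, geno, third_hits=max(extra, 0))


def hit_probabilities(
    regional_m: Sequence[float] | pd.Series,
    loh_ratio_cl: float,
    loh_ratio_cn: float,
) -> pd.Series:
    """Per-hit type probabilities over (0, 1, 2, 3, '-', 'x2').

    ``regional_m`` are the truncating regional weights (sum 1); the LOH
    ratios are ``m_-/m_0`` and ``m_x2/m_0`` (e.g. from
    :func:`loh_weights_from_frequencies`).  The result is normalized to sum
    to 1 over the six types.
    """
    m = np.asarray(regional_m, dtype=float)
    if m.shape != (4,) or (m < 0).any():
        raise ValueError("regional_m must be four nonnegative weights")
    if m[0] <= 0:
        raise ValueError("m_0 must be positive to anchor the LOH ratios")
    if loh_ratio_cl < 0 or loh_ratio_cn < 0:
        raise ValueError("LOH ratios must be nonnegative")
    raw = np.concatenate([m, [loh_ratio_cl * m[0], loh_ratio_cn * m[0]]])
    return pd.Series(raw / raw.sum(), index=list(HIT_TYPES))


def genotype_mutation_probability(m: Mapping[HitType, float] | pd.Series) -> pd.Series:
    """Neutral genotype distribution over the 18 admissible classes.

    Each class (M, N) receives unnormalized mass ``K * m_M * m_N`` with
    ``K = 1`` when ``N == M`` or ``N == "x2"`` (single ordered path: CN-LOH
    can only be the second hit) and ``K = 2`` otherwise; the classes (-,-)
    and CN-LOH-first are inadmissible.  The result is normalized.
    """
    m = pd.Series(m).reindex(list(HIT_TYPES))
    if m.isna().any():
        missing = [t for t in HIT_TYPES if t not in pd.Series(m).dropna().index]
        raise ValueError(f"missing hit-type probabilities: {missing}")
    if (m < 0).any():
        raise ValueError("hit-type probabilities must be nonnegative")
    mass = []
    for M, N in GENOTYPE_CLASSES:
        K = 1.0 if (N == M or N == CN_LOH) else 2.0
        mass.append(K * m[M] * m[N])
    out = pd.Series(mass, index=list(GENOTYPE_CLASSES), dtype=float)
    total = out.sum()
    if total <= 0:
        raise ValueError("hit-type probabilities give zero admissible mass")
    return out / total


def loh_weights_from_frequencies(
    count_00: float, count_0cl: float, count_0cn: float
) -> tuple[float, float]:
    """LOH hit-rate ratios from the zero-20AAR genotype frequencies.

    Assuming genotypes (0,0), (0,-) and (0,x2) share one progression
    probability, their cohort frequencies estimate
    ``m_-/m_0 = f_(0,-) / (2 f_(0,0))`` and ``m_x2/m_0 = f_(0,x2)/f_(0,0)``.
    """
    if count_00 <= 0:
        raise ValueError("count of genotype (0,0) must be positive")
    if count_0cl < 0 or count_0cn < 0:
        raise ValueError("counts must be nonnegative")
    return count_0cl / (2.0 * count_00), count_0cn / count_00
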