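"""Somatic second-hit predictions for familial adenomatous polyposis (FAP).

FAP patients carry a germline truncating APC mutation, so tumour initiation
requires a single somatic hit on the remaining allele.  Conditional on a
germline mutation in region ``R_M``, the somatic hit is of type ``N`` with
probability proportional to ``m_N p_(M,N)``: the neutral hit-type probability
times the progression probability of the resulting biallelic genotype.  The
ordering factor of the sporadic model disappears because the germline hit is
fixed.

Published FAP tables resolve copy-number events only as "LOH", so predictions
expose a merged-LOH view alongside the full six-category distribution.
Comparison envelopes are produced by multinomial simulation at the study's
sample size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .genotypes import CL_LOH, CN_LOH, HIT_TYPES, HitType

MERGED_CATEGORIES = (0, 1, 2, 3, "LOH")


@dataclass(frozen=True)
class FapPrediction:
    """Predicted somatic-hit distribution for a germline region."""

    germline_region: int
    distribution: pd.Series  # over the six hit types

    def __post_init__(self):
        d = self.distribution
        if list(d.index) != list(HIT_TYPES):
            raise ValueError("distribution must be indexed by the six hit types")
        if (d < 0).any() or abs(d.sum() - 1) > 1e-9:
            raise ValueError("distribution must be a probability vector")

    def merged_loh(self) -> pd.Series:
        """Distribution with CL-LOH and CN-LOH pooled into one LOH category."""
        d = self.distribution
        out = pd.Series(
            [d[0], d[1], d[2], d[3], d[CL_LOH] + d[CN_LOH]],
            index=list(MERGED_CATEGORIES),
        )
        return out


def fap_somatic_distribution(
    germline_region: int,
    m: pd.Series | Mapping[HitType, float],
    p: pd.Series | Mapping[tuple, float],
) -> FapPrediction:
    """P(somatic hit type N | germline region M) ∝ m_N p_(M,N).

    ``m`` are hit-type probabilities over (0,1,2,3,'-','x2'); ``p`` is any
    (relative) progression-probability vector over the 18 genotype classes --
    normalization cancels.
    """
    if germline_region not in (0, 1, 2, 3):
        raise ValueError("germline region must be 0-3")
    m = pd.Series(m).reindex(list(HIT_TYPES))
    p = pd.Series(p)
    M = germline_region
    mass = []
    for N in HIT_TYPES:
        if isinstance(N, int):
            key = (min(M, N), max(M, N))
        else:
            key = (M, N)
        p_mn = float(p.get(key, 0.0))
        mass.append(float(m[N]) * p_mn)
    mass = pd.Series(mass, index=list(HIT_TYPES), dtype=float)
    if mass.sum() <= 0:
        raise ValueError(
            f"all somatic-hit numerators are zero for germline region {M}"
        )
    return FapPrediction(M, mass / mass.sum())


def fap_envelope(
    prediction: FapPrediction | pd.Series,
    n_trials: int,
    n_sims: int = 10_000,
    seed: Optional[int] = None,
    merged: bool = False,
) -> pd.DataFrame:
    """Per-category 95% multinomial band around a predicted distribution.

    Simulates ``n_sims`` multinomial cohorts of ``n_trials`` tumours from the
    prediction and returns the 2.5/97.5 percentile band of the observed
    proportions -- the envelope against which observed FAP cohorts are
    compared, at the size of the largest contributing study.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be at least 1")
    if n_sims < 100:
        raise ValueError("n_sims must be at least 100")
    if isinstance(prediction, FapPrediction):
        dist = prediction.merged_loh() if merged else prediction.distribution
    else:
        dist = prediction
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n_trials, dist.to_numpy(), size=n_sims) / n_trials
    lo, hi = np.percentile(draws, [2.5, 97.5], axis=0)
    return pd.DataFrame(
        {"predicted": dist.to_numpy(), "lower": lo, "upper": hi}, index=dist.index
    )
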