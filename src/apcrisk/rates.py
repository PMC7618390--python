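"""Absolute APC mutation rates and expected double-mutant arrivals.

Converts the per-base-pair substitution rate of colonic stem cells into the
rate of truncating APC mutations per cell per year, splits it across regions
with the regional weights, derives the copy-loss and copy-neutral LOH rates
from the zero-20AAR genotype frequencies, and evaluates the expected number
of biallelic APC-mutant arrivals Lambda(t) under a Poisson model of mutation
accumulation in the colonic crypt population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

#: Printed colonic-crypt constants: per-bp SBS rate per year, analysis-window
#: length (bp upstream of the first SAMP repeat), stop-gain fraction of SBSs
#: and the stop-gain:frameshift ratio.
SBS_RATE_PER_BP_YEAR = 1.45e-8
APC_WINDOW_BP = 4717
STOP_FRACTION = 0.052
STOP_TO_FRAMESHIFT_RATIO = 15 / 11


def truncation_rate(
    sbs_rate_per_bp_year: float = SBS_RATE_PER_BP_YEAR,
    window_bp: float = APC_WINDOW_BP,
    stop_fraction: float = STOP_FRACTION,
    stop_to_frameshift_ratio: float = STOP_TO_FRAMESHIFT_RATIO,
) -> float:
    """Rate of truncating APC mutations per cell per year.

    ``mu_APC = rate * window * stop_fraction * (1 + 1/ratio)``: the stop-gain
    channel scaled up by the frameshift channel via the stop:frameshift
    ratio.  With the printed constants this is ~6.2e-6.
    """
    if min(sbs_rate_per_bp_year, window_bp, stop_to_frameshift_ratio) <= 0:
        raise ValueError("rate, window and ratio must be positive")
    if stop_fraction < 0:
        raise ValueError("stop fraction must be nonnegative")
    return (
        sbs_rate_per_bp_year
        * window_bp
        * stop_fraction
        * (1.0 + 1.0 / stop_to_frameshift_ratio)
    )


@dataclass(frozen=True)
class RateSet:
    """Absolute APC hit rates per cell per year, with provenance constants."""

    mu_apc: float
    mu_regions: pd.Series  # indexed R0..R3
    mu_cl_loh: float
    mu_cn_loh: float
    provenance: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.mu_apc <= 0 or (self.mu_regions <= 0).any():
            raise ValueError("all rates must be positive")
        if not np.isclose(self.mu_regions.sum(), self.mu_apc, rtol=1e-9):
            raise ValueError("regional rates must sum to mu_APC")

    def regional_weights(self) -> pd.Series:
        return self.mu_regions / self.mu_apc

    def as_dict(self) -> dict:
        return {
            "mu_apc": self.mu_apc,
            "mu_regions": self.mu_regions.to_dict(),
            "mu_cl_loh": self.mu_cl_loh,
            "mu_cn_loh": self.mu_cn_loh,
            "provenance": dict(self.provenance),
        }


def derived_rates(
    mu_apc: float,
    regional_m: Sequence[float] | pd.Series,
    loh_frequency_ratios: tuple[float, float],
    provenance: Optional[Mapping[str, float]] = None,
) -> RateSet:
    """Split mu_APC by region and derive the LOH rates.

    ``loh_frequency_ratios`` are the cohort frequency ratios
    ``(f_(0,-)/f_(0,0), f_(0,x2)/f_(0,0))``; assuming the zero-20AAR
    genotypes share one progression probability these give
    ``mu_- = ratio_cl * mu_0 / 2`` and ``mu_x2 = ratio_cn * mu_0`` (CN-LOH
    occurs only as a second hit, so its ratio enters unhalved).
    """
    m = pd.Series(np.asarray(regional_m, dtype=float))
    if isinstance(regional_m, pd.Series):
        m.index = regional_m.index
    else:
        m.index = [f"R{j}" for j in range(len(m))]
    if not np.isclose(m.sum(), 1.0, atol=1e-6):
        raise ValueError("regional weights must sum to 1")
    r_cl, r_cn = loh_frequency_ratios
    if r_cl < 0 or r_cn < 0:
        raise ValueError("frequency ratios must be nonnegative")
    mu_regions = mu_apc * m
    mu0 = float(mu_regions.iloc[0])
    return RateSet(
        mu_apc=mu_apc,
        mu_regions=mu_regions,
        mu_cl_loh=r_cl * mu0 / 2.0,
        mu_cn_loh=r_cn * mu0,
        provenance=dict(provenance or {}),
    )


@dataclass(frozen=True)
class ArrivalParams:
    """Crypt-population parameters for the arrival process.

    ``n_crypts``: total colonic crypts; ``stem_cells_per_crypt``: effective
    stem cells per crypt; ``fixation_probability``: probability a single
    mutation fixes in its crypt.  No defaults: these are not printed in the
    sources this package models, so they must be supplied.
    """

    n_crypts: float
    stem_cells_per_crypt: float
    fixation_probability: float

    def __post_init__(self):
        if min(self.n_crypts, self.stem_cells_per_crypt, self.fixation_probability) <= 0:
            raise ValueError("all arrival parameters must be positive")
        if self.fixation_probability > 1:
            raise ValueError("fixation probability cannot exceed 1")


def expected_arrivals(t: float, params: ArrivalParams, rates: RateSet) -> float:
    """Expected number of biallelic APC-mutant arrivals by age ``t`` (years).

    ``Lambda(t) = n_s^2 N p_f t^2 (mu_APC^2 + 2 mu_- mu_APC + mu_x2 mu_APC)/2``;
    quadratic in ``t``, with the CN-LOH path entering through a single
    ordering since CN-LOH can only be the second hit.
    """
    if t < 0:
        raise ValueError("age t must be nonnegative")
    bracket = (
        rates.mu_apc**2
        + 2.0 * rates.mu_cl_loh * rates.mu_apc
        + rates.mu_cn_loh * rates.mu_apc
    )
    return (
        params.stem_cells_per_crypt**2
        * params.n_crypts
        * params.fixation_probability
        * t**2
        * bracket
        / 2.0
    )
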