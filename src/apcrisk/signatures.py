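"""Mutational-signature models and region-specific truncation probabilities.

Combines signature definition matrices (COSMIC-format, types x signatures),
averaged per-sample exposures, and the opportunity table of a CDS into the
regional weights ``m_j``: the probability that a new truncating mutation falls
in region ``R_j``, conditional on being truncating.  The stop-gain/frameshift
balance between the SBS and indel channels is set exogenously through a
:class:`TruncationMix` (24:1 SBS:indel in microsatellite-stable colon, 10:1
in MSI).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .cds import INDEL_TYPES, SBS96_TYPES, OpportunityTable

_ATOL = 1e-9

#: Signatures ubiquitous (>85% of samples) in healthy colonic crypts.
MSS_CRYPT_SBS = ("SBS1", "SBS5", "SBS18")
MSS_CRYPT_ID = ("ID1", "ID2", "ID5")

#: Exogenous channel balances: SBS:indel counts per context.
SBS_TO_INDEL_RATIO = {"MSS": 24.0, "proximal": 24.0, "distal": 24.0, "MSI": 10.0}

#: Fraction of SBSs that create stop codons / of indels that shift the frame.
STOP_FRACTION_OF_SBS = 0.052
FRAMESHIFT_FRACTION_OF_INDELS = 0.88


@dataclass(frozen=True)
class TruncationMix:
    """Probability that a truncating mutation is a stop gain vs a frameshift."""

    p_stop_gain: float
    p_frameshift: float

    def __post_init__(self):
        for v in (self.p_stop_gain, self.p_frameshift):
            if not 0 <= v <= 1:
                raise ValueError(f"mixture probability {v} outside [0, 1]")
        if abs(self.p_stop_gain + self.p_frameshift - 1) > 1e-9:
            raise ValueError("mixture probabilities must sum to 1")

    @classmethod
    def from_rates(
        cls,
        sbs_to_indel_ratio: float,
        stop_fraction_of_sbs: float = STOP_FRACTION_OF_SBS,
        frameshift_fraction_of_indels: float = FRAMESHIFT_FRACTION_OF_INDELS,
    ) -> "TruncationMix":
        """Mix implied by an SBS:indel ratio and per-channel truncating fractions.

        ``p_stop ∝ ratio × stop_fraction`` and ``p_frameshift ∝ 1 × frameshift
        fraction``.  With the colonic-crypt inputs (24, 0.052, 0.88) this gives
        approximately the 15:11 stop-gain:frameshift balance.
        """
        if sbs_to_indel_ratio <= 0:
            raise ValueError("SBS:indel ratio must be positive")
        if stop_fraction_of_sbs < 0 or frameshift_fraction_of_indels < 0:
            raise ValueError("truncating fractions must be nonnegative")
        stop = sbs_to_indel_ratio * stop_fraction_of_sbs
        fs = frameshift_fraction_of_indels
        total = stop + fs
        if total == 0:
            raise ValueError("both channels have zero truncating mass")
        return cls(stop / total, fs / total)

    @classmethod
    def from_stop_frameshift_ratio(cls, stop: float, frameshift: float) -> "TruncationMix":
        """Mix from a direct stop-gain:frameshift ratio, e.g. (15, 11)."""
        if stop < 0 or frameshift < 0 or stop + frameshift == 0:
            raise ValueError("ratio parts must be nonnegative and not both zero")
        return cls(stop / (stop + frameshift), frameshift / (stop + frameshift))

    @classmethod
    def stop_gain_only(cls) -> "TruncationMix":
        """The POLE-deficient limit: no frameshift channel."""
        return cls(1.0, 0.0)


def average_exposures(
    per_sample_exposures: pd.DataFrame, inclusion_threshold: float = 0.85
) -> pd.Series:
    """Average per-sample signature exposures into a single weight vector.

    Signatures with nonzero load in less than ``inclusion_threshold`` of
    samples are dropped (default keeps signatures present in >=85% of
    samples); each retained row is normalized to sum to 1, rows are averaged,
    and the mean is renormalized.
    """
    exp = per_sample_exposures.astype(float)
    if (exp.values < 0).any():
        raise ValueError("exposures must be nonnegative")
    if exp.empty or not (exp.values > 0).any():
        raise ValueError("exposure table is empty or all-zero")
    presence = (exp > 0).mean(axis=0)
    kept = presence[presence >= inclusion_threshold].index
    if len(kept) == 0:
        raise ValueError(
            f"no signature is present in >= {inclusion_threshold:.0%} of samples"
        )
    exp = exp[kept]
    row_sums = exp.sum(axis=1)
    exp = exp.loc[row_sums > 0].div(row_sums[row_sums > 0], axis=0)
    weights = exp.mean(axis=0)
    return weights / weights.sum()


@dataclass
class SignatureModel:
    """Signature matrices plus averaged exposure weights for a named context.

    ``sbs_signatures`` (96 x S) and ``indel_signatures`` (71 x S') are
    probability columns over the mutation-type catalogues; the exposure
    weights are per-channel and sum to 1.  The indel channel may be absent
    (POLE context, where the frameshift channel is switched off).
    """

    context_name: str
    sbs_signatures: pd.DataFrame
    sbs_weights: pd.Series
    indel_signatures: Optional[pd.DataFrame] = None
    indel_weights: Optional[pd.Series] = None

    def __post_init__(self):
        self._check_channel(self.sbs_signatures, self.sbs_weights, SBS96_TYPES, "SBS")
        if (self.indel_signatures is None) != (self.indel_weights is None):
            raise ValueError("indel signatures and weights must be given together")
        if self.indel_signatures is not None:
            self._check_channel(
                self.indel_signatures, self.indel_weights, INDEL_TYPES, "indel"
            )

    @staticmethod
    def _check_channel(matrix, weights, catalogue, name):
        if set(matrix.index) != set(catalogue):
            raise ValueError(f"{name} matrix index does not match the type catalogue")
        col_sums = matrix.sum(axis=0)
        if not np.allclose(col_sums, 1.0, atol=1e-6):
            raise ValueError(f"{name} signature columns must each sum to 1")
        if not np.isclose(weights.sum(), 1.0, atol=1e-6) or (weights < 0).any():
            raise ValueError(f"{name} exposure weights must be nonnegative and sum to 1")
        if set(weights.index) - set(matrix.columns):
            raise ValueError(f"{name} weights name signatures missing from the matrix")

    @classmethod
    def from_exposure_tables(
        cls,
        context_name: str,
        sbs_signatures: pd.DataFrame,
        sbs_exposures: pd.DataFrame,
        indel_signatures: Optional[pd.DataFrame] = None,
        indel_exposures: Optional[pd.DataFrame] = None,
        inclusion_threshold: float = 0.85,
    ) -> "SignatureModel":
        """Build a model by averaging per-sample exposures per channel."""
        sbs_w = average_exposures(sbs_exposures, inclusion_threshold)
        id_w = None
        if indel_exposures is not None:
            id_w = average_exposures(indel_exposures, inclusion_threshold)
        return cls(
            context_name=context_name,
            sbs_signatures=sbs_signatures[list(sbs_w.index)],
            sbs_weights=sbs_w,
            indel_signatures=(
                None if id_w is None else indel_signatures[list(id_w.index)]
            ),
            indel_weights=id_w,
        )

    def sbs_type_probabilities(self) -> pd.Series:
        """P(type) over the 96 SBS categories under the averaged exposures."""
        m = self.sbs_signatures[list(self.sbs_weights.index)]
        return (m * self.sbs_weights).sum(axis=1).reindex(list(SBS96_TYPES))

    def indel_type_probabilities(self) -> pd.Series:
        if self.indel_signatures is None:
            raise ValueError(f"context {self.context_name!r} has no indel channel")
        m = self.indel_signatures[list(self.indel_weights.index)]
        return (m * self.indel_weights).sum(axis=1).reindex(list(INDEL_TYPES))


@dataclass(frozen=True)
class RegionalWeights:
    """Probability that a truncating mutation falls in each region.

    ``m`` sums to 1 over the regions; per-channel conditional distributions
    are kept for reporting.
    """

    m: pd.Series
    stop_gain_by_region: pd.Series
    frameshift_by_region: Optional[pd.Series]
    mix: TruncationMix
    context_name: str = "custom"

    def __post_init__(self):
        if (self.m < -_ATOL).any() or abs(self.m.sum() - 1) > 1e-6:
            raise ValueError("regional weights must be nonnegative and sum to 1")

    def as_dict(self) -> dict:
        return {
            "context": self.context_name,
            "m": self.m.to_dict(),
            "p_stop_gain": self.mix.p_stop_gain,
            "p_frameshift": self.mix.p_frameshift,
            "stop_gain_by_region": self.stop_gain_by_region.to_dict(),
            "frameshift_by_region": (
                None
                if self.frameshift_by_region is None
                else self.frameshift_by_region.to_dict()
            ),
        }


def _channel_regional_mass(
    opportunity: pd.DataFrame, type_probs: pd.Series, regions: list[str]
) -> pd.Series:
    """Sum P(type)/compatible-loci over truncating loci, per region."""
    opp = opportunity.loc[type_probs.index]
    trunc = opp[regions]
    active = trunc.sum(axis=1) > 0
    if (active & (opp["compatible"] == 0)).any():
        bad = opp.index[active & (opp["compatible"] == 0)].tolist()
        raise ValueError(
            f"inconsistent opportunity table: truncating types with zero "
            f"compatible loci: {bad}"
        )
    per_locus = type_probs[active] / opp.loc[active, "compatible"]
    mass = trunc.loc[active].mul(per_locus, axis=0).sum(axis=0)
    return mass


def regional_weights(
    opportunities: OpportunityTable,
    sig: SignatureModel,
    mix: TruncationMix,
) -> RegionalWeights:
    """Regional truncation probabilities ``m_j`` for a signature context.

    For each mutation type the signature-averaged probability is divided by
    its compatible-locus count, summed over truncating loci per region and
    class, the per-class distributions are normalized over regions, and the
    classes are combined with the stop-gain/frameshift mixture.
    """
    regions = list(opportunities.region_names)
    stop_mass = _channel_regional_mass(
        opportunities.sbs, sig.sbs_type_probabilities(), regions
    )
    if stop_mass.sum() <= 0:
        raise ValueError("no stop-gain mass in any region under this signature model")
    p_stop_region = stop_mass / stop_mass.sum()

    if mix.p_frameshift > 0:
        fs_mass = _channel_regional_mass(
            opportunities.indel, sig.indel_type_probabilities(), regions
        )
        if fs_mass.sum() <= 0:
            raise ValueError("no frameshift mass in any region under this signature model")
        p_fs_region = fs_mass / fs_mass.sum()
    else:
        p_fs_region = None

    m = mix.p_stop_gain * p_stop_region
    if p_fs_region is not None:
        m = m + mix.p_frameshift * p_fs_region
    m = m / m.sum()
    return RegionalWeights(
        m=m,
        stop_gain_by_region=p_stop_region,
        frameshift_by_region=p_fs_region,
        mix=mix,
        context_name=sig.context_name,
    )
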