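"""Coding-sequence context for a tumour-suppressor gene.

Represents the CDS of a gene together with its functional region structure
(codon intervals between the beta-catenin-binding 20-amino-acid repeats of
APC, by default), classifies single-base substitutions into the 96
trinucleotide (SBS96) categories and small indels into a 71-category,
microhomology-free COSMIC-style indel catalogue, and exhaustively enumerates
the truncation "opportunities" of the sequence: for every mutation type, how
many loci are compatible with it and how many of those events would create a
premature stop codon or a frameshift in each region.

All coordinates are CDS-relative and 1-based, on the coding strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: Printed codon intervals between the 20AARs of APC; the analysis window
#: ends at the first SAMP repeat (codon 1569).  Inclusive 1-based bounds.
DEFAULT_REGIONS: dict[str, tuple[int, int]] = {
    "R0": (1, 1256),
    "R1": (1257, 1370),
    "R2": (1371, 1486),
    "R3": (1487, 1569),
}

DOWNSTREAM = "downstream"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def _sbs96_labels() -> tuple[str, ...]:
    labels = []
    for ref in "CT":
        for alt in "ACGT":
            if alt == ref:
                continue
            for five in "ACGT":
                for three in "ACGT":
                    labels.append(f"{five}[{ref}>{alt}]{three}")
    return tuple(labels)


#: The 96 canonical pyrimidine-centred substitution categories.
SBS96_TYPES: tuple[str, ...] = _sbs96_labels()


def _indel_labels() -> tuple[str, ...]:
    """71-category indel catalogue: COSMIC-style, without microhomology classes.

    1 bp events are classified by the (pyrimidine-collapsed) base and the
    length of the homopolymer they hit; longer events by length class
    (2,3,4,5+) and the tandem-repeat count of the deleted/inserted unit.
    Repeat bins for 5+ bp deletions are capped at 5+, which yields the
    71-category catalogue used throughout.
    """
    labels = []
    for b in "CT":
        labels += [f"1:Del:{b}:{k}" for k in range(1, 7)]  # run length 1..6+
    for b in "CT":
        labels += [f"1:Ins:{b}:{k}" for k in range(0, 6)]  # existing run 0..5+
    for ln in (2, 3, 4):
        labels += [f"{ln}:Del:R:{k}" for k in range(1, 7)]  # tandem copies 1..6+
    labels += [f"5:Del:R:{k}" for k in range(1, 6)]  # tandem copies 1..5+
    for ln in (2, 3, 4, 5):
        labels += [f"{ln}:Ins:R:{k}" for k in range(0, 6)]  # existing copies 0..5+
    return tuple(labels)


INDEL_TYPES: tuple[str, ...] = _indel_labels()

#: Length cap for modelled multi-base indels; longer events bin into the cap.
INDEL_LENGTH_CAP = 5


class MicrohomologyDeletionError(ValueError):
    """Raised for deletions flanked by partial (microhomology) repeats.

    These categories are excluded from the catalogue (they account for <5% of
    indels in colonic crypts); callers typically drop the event.
    """


@dataclass(frozen=True)
class CdsContext:
    """A coding sequence plus its region structure.

    Parameters
    ----------
    sequence
        Coding-strand CDS, A/C/G/T only, length divisible by 3.
    regions
        Ordered mapping of region name -> inclusive 1-based codon interval.
        Regions must be contiguous, start at codon 1 and fit in the CDS.
        Codons past the last region are "downstream" and excluded from the
        analysis window.
    """

    sequence: str
    regions: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_REGIONS)
    )

    def __post_init__(self):
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if set(seq) - set(BASES):
            bad = sorted(set(seq) - set(BASES))
            raise ValueError(f"sequence contains non-ACGT characters: {bad}")
        if len(seq) % 3 != 0:
            raise ValueError(f"CDS length {len(seq)} is not divisible by 3")
        prev_hi = 0
        for name, (lo, hi) in self.regions.items():
            if lo != prev_hi + 1:
                raise ValueError(f"region {name} does not start at codon {prev_hi + 1}")
            if hi < lo:
                raise ValueError(f"region {name} has empty interval [{lo}, {hi}]")
            prev_hi = hi
        if prev_hi > self.codon_count:
            raise ValueError(
                f"regions extend to codon {prev_hi} but CDS has {self.codon_count} codons"
            )

    @property
    def codon_count(self) -> int:
        return len(self.sequence) // 3

    @property
    def cutoff_codon(self) -> int:
        """Last codon of the analysis window (first SAMP codon for APC)."""
        return max(hi for _, hi in self.regions.values())

    @property
    def region_names(self) -> tuple[str, ...]:
        return tuple(self.regions)

    def codon(self, codon_index: int) -> str:
        """The codon (triplet) at a 1-based codon index."""
        if not 1 <= codon_index <= self.codon_count:
            raise ValueError(f"codon {codon_index} outside CDS (1..{self.codon_count})")
        i = 3 * (codon_index - 1)
        return self.sequence[i : i + 3]

    def codon_of_position(self, cds_pos: int) -> int:
        if not 1 <= cds_pos <= len(self.sequence):
            raise ValueError(f"position {cds_pos} outside CDS (1..{len(self.sequence)})")
        return (cds_pos - 1) // 3 + 1


def region_of_codon(codon: int, ctx: CdsContext) -> str:
    """Region label of a 1-based codon index, or ``"downstream"`` past the cutoff."""
    if not 1 <= codon <= ctx.codon_count:
        raise ValueError(f"codon {codon} outside CDS (1..{ctx.codon_count})")
    for name, (lo, hi) in ctx.regions.items():
        if lo <= codon <= hi:
            return name
    return DOWNSTREAM


def _run_length_at(seq: str, i0: int) -> int:
    """Length of the maximal homopolymer run covering 0-based index ``i0``."""
    b = seq[i0]
    lo = i0
    while lo > 0 and seq[lo - 1] == b:
        lo -= 1
    hi = i0
    while hi + 1 < len(seq) and seq[hi + 1] == b:
        hi += 1
    return hi - lo + 1


def _adjacent_run(seq: str, gap0: int, base: str) -> int:
    """Existing homopolymer of ``base`` touching the insertion gap.

    ``gap0`` is the 0-based index of the base *before* which insertion occurs.
    """
    n = 0
    i = gap0 - 1
    while i >= 0 and seq[i] == base:
        n += 1
        i -= 1
    i = gap0
    while i < len(seq) and seq[i] == base:
        n += 1
        i += 1
    return n


def _tandem_copies_deletion(seq: str, start0: int, length: int) -> int:
    """Copies of the deleted unit in a tandem array, including the deleted one."""
    unit = seq[start0 : start0 + length]
    n = 1
    i = start0 - length
    while i >= 0 and seq[i : i + length] == unit:
        n += 1
        i -= length
    i = start0 + length
    while i + length <= len(seq) and seq[i : i + length] == unit:
        n += 1
        i += length
    return n


def _tandem_copies_insertion(seq: str, gap0: int, unit: str) -> int:
    """Existing copies of ``unit`` in tandem around an insertion gap."""
    ln = len(unit)
    n = 0
    i = gap0 - ln
    while i >= 0 and seq[i : i + ln] == unit:
        n += 1
        i -= ln
    i = gap0
    while i + ln <= len(seq) and seq[i : i + ln] == unit:
        n += 1
        i += ln
    return n


def _microhomology_length(seq: str, start0: int, length: int) -> int:
    """Longest partial-repeat overlap flanking a deleted segment."""
    unit = seq[start0 : start0 + length]
    right = seq[start0 + length : start0 + 2 * length - 1]
    mh_r = 0
    while mh_r < len(right) and mh_r < length - 1 and unit[mh_r] == right[mh_r]:
        mh_r += 1
    left = seq[max(0, start0 - (length - 1)) : start0]
    mh_l = 0
    while (
        mh_l < len(left)
        and mh_l < length - 1
        and unit[length - 1 - mh_l] == left[len(left) - 1 - mh_l]
    ):
        mh_l += 1
    return max(mh_r, mh_l)


def classify_sbs(ctx: CdsContext, cds_pos: int, alt: str) -> tuple[str, bool, str]:
    """Classify a single-base substitution.

    Returns ``(sbs96_type, is_stop_gain, region)``.  The type follows the
    pyrimidine-centred convention: purine-reference changes are
    reverse-complemented together with their trinucleotide context.  Stop gain
    is true iff the substitution converts a non-stop codon into TAA/TAG/TGA.
    """
    seq = ctx.sequence
    if alt not in BASES:
        raise ValueError(f"alt allele {alt!r} is not one of A/C/G/T")
    if not 1 < cds_pos < len(seq):
        raise ValueError(
            f"position {cds_pos} lacks a 5' or 3' flank within the CDS "
            f"(valid range 2..{len(seq) - 1})"
        )
    ref = seq[cds_pos - 1]
    if alt == ref:
        raise ValueError(f"alt equals reference base {ref!r} at position {cds_pos}")
    context = seq[cds_pos - 2 : cds_pos + 1]
    if ref in "CT":
        label = f"{context[0]}[{ref}>{alt}]{context[2]}"
    else:
        rc = revcomp(context)
        label = f"{rc[0]}[{rc[1]}>{alt.translate(_COMPLEMENT)}]{rc[2]}"
    codon_idx = ctx.codon_of_position(cds_pos)
    codon = ctx.codon(codon_idx)
    within = (cds_pos - 1) % 3
    mutant = codon[:within] + alt + codon[within + 1 :]
    is_stop_gain = mutant in STOP_CODONS and codon not in STOP_CODONS
    return label, is_stop_gain, region_of_codon(codon_idx, ctx)


def _normalize_indel(ctx: CdsContext, cds_pos: int, ref_allele: str, alt_allele: str):
    """Reduce a possibly VCF-anchored indel to a pure insertion or deletion."""
    ref = (ref_allele or "").upper().replace("-", "")
    alt = (alt_allele or "").upper().replace("-", "")
    pos = cds_pos
    while ref and alt and ref[0] == alt[0]:
        ref, alt, pos = ref[1:], alt[1:], pos + 1
    if ref and alt:
        raise ValueError(
            f"unsupported indel at {cds_pos}: complex substitution {ref_allele}>{alt_allele}"
        )
    if not ref and not alt:
        raise ValueError(f"empty indel at {cds_pos}: {ref_allele}>{alt_allele}")
    return pos, ref, alt


def classify_indel(
    ctx: CdsContext, cds_pos: int, ref_allele: str, alt_allele: str
) -> tuple[str, bool, str]:
    """Classify a small insertion or deletion.

    Accepts either pure alleles (deletion: ``ref`` = deleted bases, ``alt``
    empty; insertion vice versa) or VCF-style anchored alleles.  Returns
    ``(indel_type, is_frameshift, region)``; the region is that of the first
    affected codon.  Deletions flanked by partial repeats raise
    :class:`MicrohomologyDeletionError` after emitting a warning.
    """
    seq = ctx.sequence
    pos, ref, alt = _normalize_indel(ctx, cds_pos, ref_allele, alt_allele)
    if ref:  # deletion
        length = len(ref)
        start0 = pos - 1
        if start0 < 0 or start0 + length > len(seq):
            raise ValueError(f"deletion at {pos} extends outside the CDS")
        if seq[start0 : start0 + length] != ref:
            raise ValueError(
                f"reference mismatch at {pos}: CDS has "
                f"{seq[start0:start0 + length]!r}, got {ref!r}"
            )
        frameshift = length % 3 != 0
        region = region_of_codon(ctx.codon_of_position(pos), ctx)
        if length == 1:
            b = "T" if ref in "AT" else "C"
            run = _run_length_at(seq, start0)
            return f"1:Del:{b}:{min(run, 6)}", frameshift, region
        copies = _tandem_copies_deletion(seq, start0, length)
        if copies == 1 and _microhomology_length(seq, start0, length) >= 1:
            warnings.warn(
                f"deletion at {pos} ({length} bp) is a microhomology event; "
                "not in the 71-type catalogue",
                stacklevel=2,
            )
            raise MicrohomologyDeletionError(
                f"microhomology deletion at {pos} excluded from catalogue"
            )
        ln = min(length, INDEL_LENGTH_CAP)
        cap = 5 if ln == 5 else 6
        return f"{ln}:Del:R:{min(copies, cap)}", frameshift, region
    # insertion of `alt` beginning at CDS position `pos`
    length = len(alt)
    gap0 = pos - 1
    if not 0 <= gap0 <= len(seq):
        raise ValueError(f"insertion point {pos} outside the CDS")
    frameshift = length % 3 != 0
    first_codon = ctx.codon_of_position(min(pos, len(seq)))
    region = region_of_codon(first_codon, ctx)
    if length == 1:
        b = "T" if alt in "AT" else "C"
        run = _adjacent_run(seq, gap0, alt)
        return f"1:Ins:{b}:{min(run, 5)}", frameshift, region
    copies = _tandem_copies_insertion(seq, gap0, alt)
    ln = min(length, INDEL_LENGTH_CAP)
    return f"{ln}:Ins:R:{min(copies, 5)}", frameshift, region


@dataclass
class OpportunityTable:
    """Per-mutation-type compatible-locus and truncation counts.

    ``sbs`` and ``indel`` are DataFrames indexed by the respective type
    catalogue, with a ``compatible`` column (number of loci at which the type
    can occur inside the analysis window) and one column per region counting
    the truncating events (stop gains for SBS, frameshifts for indels).
    """

    sbs: pd.DataFrame
    indel: pd.DataFrame
    region_names: tuple[str, ...]

    def validate(self) -> None:
        for df in (self.sbs, self.indel):
            trunc = df[list(self.region_names)].sum(axis=1)
            if (trunc > df["compatible"]).any():
                raise ValueError("truncating counts exceed compatible-locus counts")

    @property
    def stop_gain_by_region(self) -> pd.Series:
        return self.sbs[list(self.region_names)].sum(axis=0)

    @property
    def frameshift_by_region(self) -> pd.Series:
        return self.indel[list(self.region_names)].sum(axis=0)


def enumerate_opportunities(ctx: CdsContext) -> OpportunityTable:
    """Exhaustively enumerate mutation opportunities in the analysis window.

    SBS: every CDS position with both flanks, times the three alternative
    bases.  Indels: deletions of 1..5 bp at every start position, 1 bp
    insertions of every base at every junction, and for each multi-base length
    one tandem-duplication event plus one novel-sequence event per junction.
    Microhomology deletions are excluded.  Deterministic.
    """
    seq = ctx.sequence
    regions = list(ctx.region_names)
    window_end = min(3 * ctx.cutoff_codon, len(seq))

    sbs = pd.DataFrame(0, index=list(SBS96_TYPES), columns=["compatible"] + regions)
    for pos in range(2, min(window_end, len(seq) - 1) + 1):
        ref = seq[pos - 1]
        for alt in BASES:
            if alt == ref:
                continue
            label, stop, region = classify_sbs(ctx, pos, alt)
            sbs.at[label, "compatible"] += 1
            if stop and region != DOWNSTREAM:
                sbs.at[label, region] += 1

    indel = pd.DataFrame(0, index=list(INDEL_TYPES), columns=["compatible"] + regions)

    def _count(label: str, frameshift: bool, region: str) -> None:
        indel.at[label, "compatible"] += 1
        if frameshift and region != DOWNSTREAM:
            indel.at[label, region] += 1

    for length in range(1, INDEL_LENGTH_CAP + 1):
        for pos in range(1, window_end - length + 2):
            ref = seq[pos - 1 : pos - 1 + length]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    label, fs, region = classify_indel(ctx, pos, ref, "")
                except MicrohomologyDeletionError:
                    continue
            _count(label, fs, region)

    for pos in range(1, window_end + 1):
        gap0 = pos - 1
        for b in BASES:
            label, fs, region = classify_indel(ctx, pos, "", b)
            _count(label, fs, region)
        for length in range(2, INDEL_LENGTH_CAP + 1):
            fs = length % 3 != 0
            region = region_of_codon(ctx.codon_of_position(pos), ctx)
            if gap0 - length >= 0:  # tandem duplication of the preceding unit
                unit = seq[gap0 - length : gap0]
                label, fs2, region2 = classify_indel(ctx, pos, "", unit)
                _count(label, fs2, region2)
            _count(f"{length}:Ins:R:0", fs, region)  # novel (non-repeat) insertion

    table = OpportunityTable(sbs=sbs, indel=indel, region_names=tuple(regions))
    table.validate()
    return table
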