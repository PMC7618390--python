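"""CDS regions, substitution/indel classification, opportunity enumeration."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from apcrisk.cds import (
    DEFAULT_REGIONS,
    INDEL_TYPES,
    SBS96_TYPES,
    STOP_CODONS,
    CdsContext,
    MicrohomologyDeletionError,
    classify_indel,
    classify_sbs,
    enumerate_opportunities,
    region_of_codon,
    revcomp,
)


class TestRegions:
    @pytest.mark.parametrize(
        "codon,expected",
        [
            (800, "R0"),
            (1, "R0"),
            (1256, "R0"),
            (1257, "R1"),
            (1370, "R1"),
            (1371, "R2"),
            (1486, "R2"),
            (1487, "R3"),
            (1569, "R3"),
            (1600, "downstream"),
        ],
    )
    def test_printed_region_bounds(self, apc_regions_ctx, codon, expected):
        assert region_of_codon(codon, apc_regions_ctx) == expected

    def test_out_of_cds_codon_names_index(self, apc_regions_ctx):
        with pytest.raises(ValueError, match="9999"):
            region_of_codon(9999, apc_regions_ctx)

    def test_invalid_context_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            CdsContext("ATGC", regions={"R0": (1, 1)})
        with pytest.raises(ValueError, match="non-ACGT"):
            CdsContext("ATGNNA", regions={"R0": (1, 2)})
        with pytest.raises(ValueError, match="start at codon"):
            CdsContext("ATG" * 10, regions={"R0": (1, 3), "R1": (5, 8)})


class TestClassifySbs:
    # positions:   123456789012
    SEQ = "ATGTCATGGAAA"  # codons ATG TCA TGG AAA
    CTX = CdsContext(SEQ, regions={"R0": (1, 4)})

    def test_pyrimidine_centred_label(self):
        label, stop, region = classify_sbs(self.CTX, 5, "A")
        assert label == "T[C>A]A"
        assert stop  # TCA -> TAA
        assert region == "R0"

    def test_purine_reference_is_reverse_complemented(self):
        # G in context AGT; coding-strand G>T collapses to A[C>A]T
        ctx = CdsContext("ATGAGTCAAAAA", regions={"R0": (1, 4)})
        label, _, _ = classify_sbs(ctx, 5, "T")
        assert label == "A[C>A]T"

    def test_trp_codon_stop_gain(self):
        # TGG -> TGA via G>A at the third codon position
        label, stop, _ = classify_sbs(self.CTX, 9, "A")
        assert stop
        # TGG -> TGC is not a stop
        _, stop2, _ = classify_sbs(self.CTX, 9, "C")
        assert not stop2

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="A/C/G/T"):
            classify_sbs(self.CTX, 5, "N")
        with pytest.raises(ValueError, match="equals reference"):
            classify_sbs(self.CTX, 5, "C")
        with pytest.raises(ValueError, match="flank"):
            classify_sbs(self.CTX, 1, "C")


class TestClassifyIndel:
    def test_deletion_in_long_t_homopolymer(self, toy_ctx):
        # any single-T deletion inside the planted 7-T run collapses into the
        # long-homopolymer class
        pos = 3 * (52 - 1) + 1  # first nucleotide of codon 52
        label, fs, region = classify_indel(toy_ctx, pos + 3, "T", "")
        assert label == "1:Del:T:6"
        assert fs
        assert region == "R3"

    def test_in_frame_deletion_not_frameshift(self):
        ctx = CdsContext("ATGAAACCCGGGTAC", regions={"R0": (1, 5)})
        _, fs, _ = classify_indel(ctx, 7, "CCC", "")
        assert fs is False

    def test_insertion_without_flanking_repeat(self):
        ctx = CdsContext("ATGTCGTCGTCG", regions={"R0": (1, 4)})
        # insert A before position 2 (flanks A and T; no A run on the right)
        label, fs, region = classify_indel(ctx, 2, "", "A")
        assert label == "1:Ins:T:1"  # one adjacent A (position 1), collapsed to T
        assert fs
        # G inserted where no G is adjacent -> repeat bin 0
        label2, _, _ = classify_indel(ctx, 5, "", "G")
        assert label2 == "1:Ins:C:0"

    def test_vcf_anchored_alleles_accepted(self):
        ctx = CdsContext("ATGTTTTTTTCA", regions={"R0": (1, 4)})
        label, fs, _ = classify_indel(ctx, 3, "GT", "G")  # del one T of the run
        assert label == "1:Del:T:6"
        assert fs

    def test_complex_substitution_rejected(self, toy_ctx):
        with pytest.raises(ValueError, match="unsupported indel"):
            classify_indel(toy_ctx, 5, "ACG", "TT")

    def test_microhomology_deletion_rejected_with_warning(self):
        #            123456789...
        ctx = CdsContext("ATGCTAGCTAAT", regions={"R0": (1, 4)})
        # deleting CTAG at position 4 leaves CTA... sharing a 3-bp prefix
        with pytest.warns(UserWarning, match="microhomology"):
            with pytest.raises(MicrohomologyDeletionError):
                classify_indel(ctx, 4, "CTAG", "")

    @settings(max_examples=200, derandomize=True)
    @given(
        length=st.integers(min_value=1, max_value=9),
        kind=st.sampled_from(["ins", "del"]),
        seed=st.integers(min_value=0, max_value=500),
    )
    def test_frameshift_depends_only_on_length_mod_3(self, length, kind, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=36))
        try:
            ctx = CdsContext(seq, regions={"R0": (1, 12)})
        except ValueError:
            return  # random sequence may contain a region violation; irrelevant
        pos = int(rng.integers(1, 36 - length))
        if kind == "del":
            alleles = (seq[pos - 1 : pos - 1 + length], "")
        else:
            alleles = ("", "".join(rng.choice(list("ACGT"), size=length)))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, fs, _ = classify_indel(ctx, pos, *alleles)
        except MicrohomologyDeletionError:
            return
        assert fs == (length % 3 != 0)


def brute_force_stop_gains_by_region(ctx):
    """Independent oracle: translate every single-base mutant, count new stops."""
    seq = ctx.sequence
    window_end = 3 * ctx.cutoff_codon
    counts = {name: 0 for name in ctx.region_names}
    for pos in range(2, min(window_end, len(seq) - 1) + 1):
        codon_idx = (pos - 1) // 3
        codon = seq[3 * codon_idx : 3 * codon_idx + 3]
        if codon in STOP_CODONS:
            continue
        offset = (pos - 1) % 3
        for alt in "ACGT":
            if alt == seq[pos - 1]:
                continue
            mutant = codon[:offset] + alt + codon[offset + 1 :]
            if mutant in STOP_CODONS:
                region = region_of_codon(codon_idx + 1, ctx)
                if region != "downstream":
                    counts[region] += 1
    return counts


class TestEnumeration:
    def test_stop_gain_counts_match_brute_force_oracle(self, toy_ctx):
        table = enumerate_opportunities(toy_ctx)
        oracle = brute_force_stop_gains_by_region(toy_ctx)
        got = table.stop_gain_by_region
        for region, expected in oracle.items():
            assert got[region] == expected

    def test_single_trp_codon_gives_two_stop_opportunities(self):
        # all other codons are CCC, which is stop-immune under any single
        # substitution, so R1's stop-gain total is exactly TAG + TGA
        codons = ["CCC"] * 30
        codons[20] = "TGG"  # inside the R1 analogue
        ctx = CdsContext(
            "".join(codons),
            regions={"R0": (1, 18), "R1": (19, 22), "R2": (23, 26), "R3": (27, 29)},
        )
        table = enumerate_opportunities(ctx)
        assert table.stop_gain_by_region["R1"] == 2
        assert table.stop_gain_by_region["R0"] == 0

    def test_region_without_stop_capable_codons_counts_zero(self):
        ctx = CdsContext("CCC" * 24, regions={"R0": (1, 12), "R1": (13, 24)})
        table = enumerate_opportunities(ctx)
        assert table.stop_gain_by_region.sum() == 0

    def test_homopolymer_deletions_collapse_with_scan_oracle(self, toy_ctx):
        table = enumerate_opportunities(toy_ctx)
        # independent scan: positions within the window whose maximal A/T run
        # is >= 6 are exactly the 1-bp deletion loci of type 1:Del:T:6
        seq = toy_ctx.sequence
        window_end = 3 * toy_ctx.cutoff_codon
        expected = 0
        for i in range(window_end):
            b = seq[i]
            if b not in "AT":
                continue
            lo = i
            while lo > 0 and seq[lo - 1] == b:
                lo -= 1
            hi = i
            while hi + 1 < len(seq) and seq[hi + 1] == b:
                hi += 1
            if hi - lo + 1 >= 6:
                expected += 1
        assert table.indel.at["1:Del:T:6", "compatible"] == expected
        assert expected >= 7  # the planted run alone contributes seven loci

    def test_truncating_counts_bounded_by_compatible(self, toy_ctx):
        table = enumerate_opportunities(toy_ctx)
        regions = list(table.region_names)
        assert (table.sbs[regions].sum(axis=1) <= table.sbs["compatible"]).all()
        assert (table.indel[regions].sum(axis=1) <= table.indel["compatible"]).all()

    def test_strand_collapse_leaves_sbs_histogram_invariant(self, toy_ctx):
        full = {"R0": (1, toy_ctx.codon_count)}
        ctx_fwd = CdsContext(toy_ctx.sequence, regions=full)
        ctx_rev = CdsContext(revcomp(toy_ctx.sequence), regions=full)
        h_fwd = enumerate_opportunities(ctx_fwd).sbs["compatible"]
        h_rev = enumerate_opportunities(ctx_rev).sbs["compatible"]
        assert (h_fwd == h_rev).all()


def test_catalogue_sizes():
    assert len(SBS96_TYPES) == 96
    assert len(set(SBS96_TYPES)) == 96
    assert len(INDEL_TYPES) == 71
    assert len(set(INDEL_TYPES)) == 71
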