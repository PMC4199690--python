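import numpy as np
import pytest

from conftest import random_cds
from cubscan.pseudogene_screen import (
    FILTER_HET,
    FILTER_LOW_COV,
    FILTER_SELF,
    FILTER_SPLICE,
    AlignedPair,
    PseudogeneCall,
    alignment_excerpt,
    detect_lesions,
    filter_coverage,
    filter_self_alignment,
    filter_splice_adjacent,
    read_aligned_pair,
)

# a lesion-free 60-nt frame: no stop codons anywhere in frame 0
CLEAN = "ATGGCCGCTGAAGATCACAAGATTCTGGTCGCTGAAGATCACAAGATTCTGGTCGCCGCA"


class TestDetectLesions:
    def test_identical_sequences_yield_no_calls(self):
        pair = AlignedPair("g", CLEAN, CLEAN)
        assert detect_lesions(pair) == []

    def test_identical_with_terminal_stop_not_called(self):
        seq = CLEAN + "TAA"
        pair = AlignedPair("g", seq, seq)
        assert detect_lesions(pair) == []

    def test_point_substitution_to_stop(self):
        # codon 3 (GAA) -> TGA: premature stop, no frameshift
        target = CLEAN[:9] + "TGA" + CLEAN[12:]
        calls = detect_lesions(AlignedPair("g", CLEAN, target))
        assert [c.lesion_type for c in calls] == ["premature_stop"]
        assert calls[0].ref_codon_index == 3
        assert calls[0].detail == "TGA"

    def test_two_nearby_stop_substitutions_both_called(self):
        target = CLEAN[:9] + "TGA" + CLEAN[12:15] + "TAA" + CLEAN[18:]
        calls = detect_lesions(AlignedPair("g", CLEAN, target))
        stops = [c for c in calls if c.lesion_type == "premature_stop"]
        assert [c.ref_codon_index for c in stops] == [3, 5]

    def test_31_nt_deletion_is_frameshift(self):
        ref = CLEAN
        start = 6
        target = ref[:start] + "-" * 31 + ref[start + 31 :]
        calls = detect_lesions(AlignedPair("g", ref, target))
        fs = [c for c in calls if c.lesion_type == "frameshift"]
        assert len(fs) == 1
        assert fs[0].detail == "-31"
        assert fs[0].ref_codon_index == 2

    def test_3_nt_deletion_preserves_frame(self):
        # remove codon 2 (CAC... actually GCT at 6..9); junction is clean
        target = CLEAN[:6] + "---" + CLEAN[9:]
        calls = detect_lesions(AlignedPair("g", CLEAN, target))
        assert [c for c in calls if c.lesion_type == "frameshift"] == []

    def test_insertion_frameshift(self):
        ref = CLEAN[:12] + "--" + CLEAN[12:]
        target = CLEAN[:12] + "GG" + CLEAN[12:]
        calls = detect_lesions(AlignedPair("g", ref, target))
        fs = [c for c in calls if c.lesion_type == "frameshift"]
        assert len(fs) == 1
        assert fs[0].detail == "+2"
        assert fs[0].ref_codon_index == 4

    def test_compensating_indels_restore_frame(self):
        # -1 at nt 12, +1 at nt 24: two frameshift records, frame clean after
        ref = CLEAN[:24] + "-" + CLEAN[24:]
        tgt = CLEAN[:12] + "-" + CLEAN[13:24] + "G" + CLEAN[24:]
        calls = detect_lesions(AlignedPair("g", ref, tgt))
        fs = [c for c in calls if c.lesion_type == "frameshift"]
        assert [c.detail for c in fs] == ["-1", "+1"]

    def test_frameshift_reveals_downstream_stop(self):
        # ref frame 0 is clean; deleting one nt brings a TAA into frame
        ref = "ATGCTAAGCAGCATG"
        tgt = "ATG-TAAGCAGCATG"
        calls = detect_lesions(AlignedPair("g", ref, tgt))
        types = [c.lesion_type for c in calls]
        assert "frameshift" in types and "premature_stop" in types

    def test_gap_vs_gap_column_rejected(self):
        with pytest.raises(ValueError, match="gap-vs-gap"):
            detect_lesions(AlignedPair("g", "ATG-AAA", "ATG-AAA"))

    def test_calls_invariant_under_terminal_padding(self):
        target = CLEAN[:9] + "TGA" + CLEAN[12:]
        base = detect_lesions(AlignedPair("g", CLEAN, target))
        pad = "GCAGCC"
        padded = detect_lesions(AlignedPair("g", CLEAN + pad, target + pad))
        assert [(c.lesion_type, c.ref_codon_index) for c in base] == [
            (c.lesion_type, c.ref_codon_index) for c in padded
        ]

    def test_leading_codon_padding_shifts_indices_by_one(self):
        target = CLEAN[:9] + "TGA" + CLEAN[12:]
        base = detect_lesions(AlignedPair("g", CLEAN, target))
        shifted = detect_lesions(AlignedPair("g", "GCC" + CLEAN, "GCC" + target))
        assert [c.ref_codon_index + 1 for c in base] == [
            c.ref_codon_index for c in shifted
        ]

    def test_unequal_gapped_lengths_rejected(self):
        with pytest.raises(ValueError, match="lengths differ"):
            AlignedPair("g", "ATGAAA", "ATG")


class TestFilters:
    def _call(self, gid="g", pos=12):
        return PseudogeneCall(
            gene_id=gid, lesion_type="premature_stop",
            ref_codon_index=pos // 3, ref_nt_pos=pos, detail="TAA",
        )

    def test_clean_self_alignment_leaves_candidate(self):
        (out,) = filter_self_alignment([self._call()], [])
        assert out.passes

    def test_dirty_self_alignment_flags_gene(self):
        (out,) = filter_self_alignment([self._call("g")], [self._call("g", 30)])
        assert FILTER_SELF in out.filters_failed

    def test_empty_candidate_list(self):
        assert filter_self_alignment([], [self._call()]) == []

    def test_lesion_near_boundary_flagged(self):
        (out,) = filter_splice_adjacent([self._call(pos=12)], boundaries=[16], window=10)
        assert FILTER_SPLICE in out.filters_failed

    def test_lesion_far_from_boundary_unflagged(self):
        (out,) = filter_splice_adjacent([self._call(pos=12)], boundaries=[62], window=10)
        assert out.passes

    def test_no_boundaries_skips_filter(self, caplog):
        with caplog.at_level("WARNING"):
            (out,) = filter_splice_adjacent([self._call()], boundaries=None)
        assert out.passes
        assert any("skipped" in r.message for r in caplog.records)

    def test_unsorted_boundaries_rejected(self):
        with pytest.raises(ValueError):
            filter_splice_adjacent([self._call()], boundaries=[30, 10])

    @pytest.mark.parametrize(
        "depth,alt_frac,expected",
        [
            (2, 1.0, {FILTER_LOW_COV}),
            (40, 0.48, {FILTER_HET}),
            (40, 1.0, set()),
            (40, 0.95, set()),
        ],
    )
    def test_coverage_rules(self, depth, alt_frac, expected):
        (out,) = filter_coverage([self._call(pos=12)], {12: (depth, alt_frac)})
        assert out.filters_failed == expected

    def test_missing_site_treated_as_low_coverage(self):
        (out,) = filter_coverage([self._call(pos=12)], {})
        assert FILTER_LOW_COV in out.filters_failed

    def test_filters_accumulate(self):
        calls = filter_self_alignment([self._call("g")], [self._call("g")])
        calls = filter_coverage(calls, {12: (1, 1.0)})
        (out,) = calls
        assert out.filters_failed == {FILTER_SELF, FILTER_LOW_COV}


class TestIO:
    def test_read_aligned_pair(self, tmp_path):
        p = tmp_path / "aln.fa"
        p.write_text(f">ref\n{CLEAN}\n>target\n{CLEAN}\n")
        pair = read_aligned_pair(p)
        assert pair.gene_id == "target"
        assert pair.ref_seq == CLEAN

    def test_wrong_record_count_rejected(self, tmp_path):
        p = tmp_path / "aln.fa"
        p.write_text(f">only\n{CLEAN}\n")
        with pytest.raises(ValueError, match="2 aligned records"):
            read_aligned_pair(p)

    def test_excerpt_marks_lesion(self):
        target = CLEAN[:9] + "TGA" + CLEAN[12:]
        pair = AlignedPair("g", CLEAN, target)
        (call,) = detect_lesions(pair)
        text = alignment_excerpt(pair, call)
        assert "premature_stop" in text and "^" in text
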