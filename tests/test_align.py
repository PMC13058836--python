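"""Adapter trimming, semi-global aligner vs full-DP oracle, mate merging."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ampliclone import align_to_amplicon, build_fragment_pileup, trim_adapter
from ampliclone.align import ReadAlignment
from ampliclone.reference import revcomp

from conftest import mutate_read, semiglobal_edit_distance

ADAPTER = "AGATCGGAAGAGC"


class TestTrimAdapter:
    def test_exact_suffix_removed(self):
        read = "ACGTACGTACGTACGTACGTGGCCTT" + ADAPTER
        assert trim_adapter(read, ADAPTER) == "ACGTACGTACGTACGTACGTGGCCTT"

    def test_no_adapter_untouched(self):
        read = "ACGTACGTCCGGTTAACCGGTTAACC"
        assert trim_adapter(read, ADAPTER) == read

    def test_partial_adapter_with_one_mismatch(self):
        """12-nt adapter prefix with 1 mismatch at the 3' end: cut at the
        match start, confirmed by a brute-force scan of every suffix."""
        prefix = "TTGCACGGTTCACCAGGTAC"
        partial = ADAPTER[:12]
        partial = partial[:5] + ("A" if partial[5] != "A" else "C") + partial[6:]
        read = prefix + partial
        # brute-force oracle: best (rate, start) over all suffix alignments
        best = None
        for start in range(len(read) - 2):
            m = min(len(ADAPTER), len(read) - start)
            mism = sum(a != b for a, b in zip(read[start : start + m], ADAPTER[:m]))
            if mism <= 0.1 * m and (best is None or mism / m < best[0]):
                best = (mism / m, start)
        assert best is not None and best[1] == len(prefix)
        assert trim_adapter(read, ADAPTER) == prefix

    def test_empty_adapter_rejected(self):
        with pytest.raises(ValueError):
            trim_adapter("ACGT", "")

    @given(st.text(alphabet="ACGT", min_size=20, max_size=60), st.integers(0, 13))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_trim_returns_prefix(self, read, keep):
        out = trim_adapter(read + ADAPTER[: keep], ADAPTER)
        assert (read + ADAPTER[:keep]).startswith(out)


class TestAlignerAgainstOracle:
    def test_error_free_read_places_exactly(self, ref):
        read = ref.sequence[50:200]
        aln = align_to_amplicon(ref, read)
        assert aln.mapped and aln.edit_distance == 0
        assert aln.amplicon_offset == 50
        assert aln.contiguous

    def test_two_substitutions_same_offset(self, ref):
        read = list(ref.sequence[50:200])
        read[30] = "A" if read[30] != "A" else "C"
        read[90] = "A" if read[90] != "A" else "C"
        aln = align_to_amplicon(ref, "".join(read))
        assert aln.edit_distance == 2
        assert aln.amplicon_offset == 50
        # oracle agreement on the same sequence
        assert semiglobal_edit_distance("".join(read), ref.sequence) == 2

    def test_reverse_complement_reads_map(self, ref):
        read = revcomp(ref.sequence[100:250])
        aln = align_to_amplicon(ref, read)
        assert aln.mapped and aln.strand == "-" and aln.edit_distance == 0
        assert aln.amplicon_offset == 100

    def test_random_reads_unmapped(self, ref):
        """Random 150-mers exceed the 20 % edit-distance threshold."""
        rng = np.random.default_rng(99)
        for _ in range(100):
            read = "".join("ACGT"[i] for i in rng.integers(0, 4, 150))
            aln = align_to_amplicon(ref, read)
            assert not aln.mapped

    def test_matches_full_dp_oracle_on_edited_short_reads(self, ref):
        """Systematic sweep: reads <= 60 nt carrying up to 6 mixed edits give
        the same semi-global distance as the naive full-DP oracle."""
        rng = np.random.default_rng(1234)
        for length in (20, 35, 60):
            for n_edits in range(7):
                for _ in range(5):
                    start = int(rng.integers(0, len(ref) - length))
                    read = mutate_read(rng, ref.sequence[start : start + length], n_edits)
                    if len(read) < 5:
                        continue
                    aln = align_to_amplicon(ref, read, try_reverse=False)
                    assert aln.edit_distance == semiglobal_edit_distance(read, ref.sequence)

    @given(st.data())
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_matches_oracle_on_random_short_queries(self, ref, data):
        read = data.draw(st.text(alphabet="ACGT", min_size=8, max_size=40))
        aln = align_to_amplicon(ref, read, try_reverse=False)
        assert aln.edit_distance == semiglobal_edit_distance(read, ref.sequence)

    def test_aligned_pairs_monotone(self, ref):
        rng = np.random.default_rng(5)
        read = mutate_read(rng, ref.sequence[40:100], 4)
        aln = align_to_amplicon(ref, read, try_reverse=False)
        pairs = aln.aligned_pairs()
        reads = [r for r, _ in pairs if r is not None]
        refs = [a for _, a in pairs if a is not None]
        assert reads == sorted(reads) and refs == sorted(refs)
        assert reads[-1] == len(read) - 1


def _contig_alignment(ref, offset, seq, qual=None):
    return ReadAlignment(
        read_id="t", amplicon_offset=offset, edit_distance=0, mapped=True,
        strand="+", cigar=f"{len(seq)}=", sequence=seq, quality=qual,
    )


class TestFragmentMerging:
    def test_non_overlapping_mates_union(self, ref):
        a1 = _contig_alignment(ref, 0, ref.sequence[:50])
        a2 = _contig_alignment(ref, 100, ref.sequence[100:150])
        calls = build_fragment_pileup(a1, a2)
        assert calls.positions.size == 100
        assert set(calls.positions) == set(range(50)) | set(range(100, 150))

    def test_overlap_agreement_counted_once(self, ref):
        a1 = _contig_alignment(ref, 0, ref.sequence[:60])
        a2 = _contig_alignment(ref, 40, ref.sequence[40:100])
        calls = build_fragment_pileup(a1, a2)
        assert calls.positions.size == 100
        assert np.unique(calls.positions).size == 100

    def test_overlap_disagreement_masked(self, ref):
        """A single discordant overlap base contributes no call at all."""
        seq2 = list(ref.sequence[40:100])
        seq2[10] = "A" if seq2[10] != "A" else "C"  # amplicon offset 50
        a1 = _contig_alignment(ref, 0, ref.sequence[:60])
        a2 = _contig_alignment(ref, 40, "".join(seq2))
        calls = build_fragment_pileup(a1, a2)
        assert calls.positions.size == 99
        assert 50 not in calls.positions

    def test_low_quality_bases_masked(self, ref):
        seq = ref.sequence[:30]
        qual = chr(33 + 30) * 15 + chr(33 + 2) * 15  # tail below Q20
        a1 = _contig_alignment(ref, 0, seq, qual)
        calls = build_fragment_pileup(a1, None, quality_floor=20)
        assert calls.positions.size == 15
        assert calls.positions.max() == 14

    def test_unmapped_fragment_flagged(self, ref):
        a1 = _contig_alignment(ref, 0, ref.sequence[:30])
        a1.mapped = False
        calls = build_fragment_pileup(a1, None)
        assert not calls.mapped and calls.positions.size == 0

    def test_deletion_read_produces_deletion_calls(self, ref):
        read = ref.sequence[20:50] + ref.sequence[53:90]  # 3 bp deletion
        aln = align_to_amplicon(ref, read, try_reverse=False)
        assert not aln.contiguous
        assert aln.edit_distance == 3
        calls = build_fragment_pileup(aln, None)
        dels = calls.positions[calls.codes == 4]
        # placement within the gap context is alignment-ambiguous; the
        # count and the neighbourhood are not
        assert dels.size == 3
        assert dels.min() >= 45 and dels.max() <= 58
        assert np.unique(calls.positions).size == calls.positions.size

    def test_insertion_tallied_separately(self, ref):
        read = ref.sequence[20:50] + "A" * 3 + ref.sequence[50:90]
        aln = align_to_amplicon(ref, read, try_reverse=False)
        calls = build_fragment_pileup(aln, None)
        assert len(calls.insertions) >= 1
        assert all(45 <= i <= 55 for i in calls.insertions)
        assert 4 not in calls.codes
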