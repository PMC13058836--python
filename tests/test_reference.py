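"""Guide geometry, coordinate mapping and codon classification."""

import numpy as np
import pytest

from ampliclone import (
    AmpliconReference,
    CodingFrame,
    DomainError,
    GuideDesign,
    ValidationError,
    adenine_run_length,
    classify_codon_edit,
    enumerate_editable_positions,
    map_protospacer_position,
    protospacer_position_at,
    validate_guide_against_reference,
)
from ampliclone.reference import revcomp

from conftest import GENETIC_CODE


class TestCoordinateMapping:
    def test_printed_anchor_coordinates(self, guide_n044):
        assert map_protospacer_position(guide_n044, 5) == ("chr7", 70768044)
        assert map_protospacer_position(guide_n044, 4) == ("chr7", 70768043)
        # anchor back-solved from the k=5 pair
        assert map_protospacer_position(guide_n044, 1) == ("chr7", 70768040)

    def test_minus_strand_mapping(self, guide_n068):
        assert map_protospacer_position(guide_n068, 5) == ("chr7", 70768068)
        assert map_protospacer_position(guide_n068, 1) == ("chr7", 70768072)

    @pytest.mark.parametrize("k", [0, 21, -3])
    def test_out_of_range_position_rejected(self, guide_n044, k):
        with pytest.raises(DomainError):
            map_protospacer_position(guide_n044, k)

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_round_trip_all_positions(self, guide_n044, guide_n068, strand):
        guide = guide_n044 if strand == "+" else guide_n068
        for k in range(1, 21):
            _, pos = map_protospacer_position(guide, k)
            assert protospacer_position_at(guide, pos) == k

    def test_minus_strand_protospacer_is_revcomp_of_reference_slice(self, ref, guide_n068):
        coords = [map_protospacer_position(guide_n068, k)[1] for k in range(1, 21)]
        plus_slice = "".join(ref.base_at(p) for p in sorted(coords))
        assert revcomp(plus_slice) == guide_n068.protospacer

    def test_guides_validate_against_reference(self, ref, guide_n044, guide_n068):
        validate_guide_against_reference(guide_n044, ref)
        validate_guide_against_reference(guide_n068, ref)

    def test_mismatching_guide_rejected(self, ref, guide_n044):
        shifted = GuideDesign(
            guide_id="bad",
            protospacer=guide_n044.protospacer,
            strand="+",
            anchor=guide_n044.anchor + 1,
            target_position=5,
            contig="chr7",
        )
        with pytest.raises(ValidationError):
            validate_guide_against_reference(shifted, ref)


class TestEditablePositions:
    def test_window_adenines(self, guide_n044, guide_n068):
        assert enumerate_editable_positions(guide_n044, (4, 7)) == [4, 5]
        assert enumerate_editable_positions(guide_n068, (4, 7)) == [5]

    def test_narrower_window(self, guide_n044):
        assert enumerate_editable_positions(guide_n044, (4, 6)) == [4, 5]
        assert enumerate_editable_positions(guide_n044, (6, 7)) == []

    def test_inverted_window_rejected(self, guide_n044):
        with pytest.raises(DomainError):
            enumerate_editable_positions(guide_n044, (7, 4))


class TestAdenineRun:
    def test_target_adenine_cluster(self, guide_n044, guide_n068):
        # N044 positions 2-5 are AAAA: a four-adenine cluster holds the target
        assert adenine_run_length(guide_n044, 5) == 4
        assert adenine_run_length(guide_n044, 2) == 4
        assert adenine_run_length(guide_n068, 5) == 1

    def test_homopolymer_guide(self):
        guide = GuideDesign(
            guide_id="polyA", protospacer="A" * 20, strand="+", anchor=100,
            target_position=1,
        )
        assert adenine_run_length(guide, 1) == 20
        assert adenine_run_length(guide, 20) == 20

    def test_non_adenine_position_rejected(self, guide_n044):
        with pytest.raises(DomainError):
            adenine_run_length(guide_n044, 1)  # position 1 is C


class TestGuideValidation:
    def test_target_must_be_adenine(self):
        with pytest.raises(ValidationError):
            GuideDesign(
                guide_id="x", protospacer="C" * 20, strand="+", anchor=1,
                target_position=5,
            )

    def test_window_bounds(self):
        with pytest.raises(DomainError):
            GuideDesign(
                guide_id="x", protospacer="A" * 20, strand="+", anchor=1,
                target_position=5, window=(0, 7),
            )


class TestCodonClassification:
    def test_printed_synonymous_edits(self, ref):
        ce = classify_codon_edit(ref, 70768044, "G")
        assert (ce.codon_before, ce.codon_after) == ("AAA", "AAG")
        assert (ce.aa_before, ce.aa_after) == ("K", "K")
        assert ce.synonymous
        ce2 = classify_codon_edit(ref, 70768068, "C")
        assert (ce2.codon_before, ce2.codon_after) == ("AGT", "AGC")
        assert (ce2.aa_before, ce2.aa_after) == ("S", "S")
        assert ce2.synonymous

    def test_identity_substitution_is_synonymous(self, ref):
        ce = classify_codon_edit(ref, 70768044, "A")
        assert ce.codon_before == ce.codon_after
        assert ce.synonymous

    def test_requires_coding_frame(self):
        bare = AmpliconReference(name="r", contig="c", genomic_start=10, sequence="ACGTAG")
        with pytest.raises(DomainError):
            classify_codon_edit(bare, 12, "G")

    def test_position_outside_amplicon_rejected(self, ref):
        with pytest.raises(DomainError):
            classify_codon_edit(ref, ref.genomic_end + 10, "G")

    def test_exhaustive_against_genetic_code_table(self):
        """Every codon x position x alt agrees with a brute-force table,
        including that third-position A->G in AAA (Lys) is synonymous."""
        bases = "ACGT"
        for codon, aa in GENETIC_CODE.items():
            amp = AmpliconReference(
                name="t", contig="c", genomic_start=1, sequence=codon,
                coding_frame=CodingFrame(0, "+"),
            )
            for pos_in_codon in range(3):
                for alt in bases:
                    ce = classify_codon_edit(amp, 1 + pos_in_codon, alt)
                    after = codon[:pos_in_codon] + alt + codon[pos_in_codon + 1 :]
                    assert ce.codon_before == codon
                    assert ce.codon_after == after
                    assert ce.aa_before == GENETIC_CODE[codon] == aa
                    assert ce.aa_after == GENETIC_CODE[after]
                    assert ce.synonymous == (GENETIC_CODE[codon] == GENETIC_CODE[after])

    def test_minus_strand_coding_frame(self):
        # plus strand TTT | minus-strand coding reads AAA (Lys); third codon
        # position of the minus-strand codon is the FIRST plus-strand base
        amp = AmpliconReference(
            name="t", contig="c", genomic_start=1, sequence="TTT",
            coding_frame=CodingFrame(0, "-"),
        )
        ce = classify_codon_edit(amp, 1, "C")  # plus T->C == minus A->G
        assert ce.codon_before == "AAA"
        assert ce.codon_after == "AAG"
        assert ce.synonymous


class TestAmpliconReference:
    def test_coordinate_identity(self, ref):
        assert ref.to_genomic(ref.to_offset(70768044)) == 70768044
        assert ref.genomic_start + len(ref) - 1 == ref.genomic_end

    def test_alphabet_enforced(self):
        with pytest.raises(ValidationError):
            AmpliconReference(name="r", contig="c", genomic_start=1, sequence="ACGN")

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValidationError):
            AmpliconReference(name="r", contig="c", genomic_start=1, sequence="")
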