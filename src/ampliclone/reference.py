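"""Reference amplicon, guide geometry and codon-level annotation.

This module defines *what an edit is*: it anchors a sequenced amplicon to
genomic coordinates, maps protospacer positions of a guide RNA onto the
genome, enumerates the adenines an adenine base editor (ABE) can deaminate
within its activity window, and classifies a substitution as synonymous or
not under the standard genetic code.

Coordinate conventions
----------------------
User-facing coordinates are 1-based inclusive genomic plus-strand positions
(``chr7:70768044`` style); internal array indices are 0-based half-open.
Protospacer positions are numbered 1-20 from the PAM-distal (5') end, the
standard convention in the base-editing literature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Optional

import numpy as np
from Bio.Seq import Seq

from .errors import DomainError, ValidationError

_DNA = set("ACGT")
COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: base letter -> internal code; code 4 is reserved for deletions in pileups
BASE_CODES = {"A": 0, "C": 1, "G": 2, "T": 3}
CODE_BASES = "ACGT"

_ENCODE_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _c in BASE_CODES.items():
    _ENCODE_LUT[ord(_b)] = _c


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string as uint8 codes 0-3."""
    return _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Decode uint8 codes 0-3 back to an ACGT string."""
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


@dataclass(frozen=True)
class CodingFrame:
    """Reading-frame annotation of an amplicon.

    ``frame_offset`` is the 0-based amplicon offset (on the plus strand for
    ``strand == '+'``, counted from the 3' end for ``strand == '-'``) of the
    first complete codon's first base.
    """

    frame_offset: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.frame_offset not in (0, 1, 2):
            raise ValidationError(f"frame_offset must be 0-2, got {self.frame_offset}")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class AmpliconReference:
    """A reference amplicon anchored to a genomic coordinate system.

    Genomic coordinate of amplicon position ``i`` (1-based within the
    amplicon) is ``genomic_start + i - 1``.
    """

    name: str
    contig: str
    genomic_start: int
    sequence: str
    coding_frame: Optional[CodingFrame] = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) < 1:
            raise ValidationError("amplicon sequence must be non-empty")
        if not set(self.sequence) <= _DNA:
            bad = sorted(set(self.sequence) - _DNA)
            raise ValidationError(f"sequence contains non-ACGT characters: {bad}")
        if self.genomic_start < 1:
            raise ValidationError("genomic_start must be a positive 1-based coordinate")

    def __len__(self) -> int:
        return len(self.sequence)

    @cached_property
    def codes(self) -> np.ndarray:
        return encode(self.sequence)

    @property
    def genomic_end(self) -> int:
        """1-based inclusive genomic coordinate of the last amplicon base."""
        return self.genomic_start + len(self.sequence) - 1

    def contains(self, position: int) -> bool:
        return self.genomic_start <= position <= self.genomic_end

    def to_offset(self, position: int) -> int:
        """Genomic 1-based coordinate -> 0-based amplicon offset."""
        if not self.contains(position):
            raise DomainError(
                f"{self.contig}:{position} outside amplicon "
                f"{self.contig}:{self.genomic_start}-{self.genomic_end}"
            )
        return position - self.genomic_start

    def to_genomic(self, offset: int) -> int:
        """0-based amplicon offset -> genomic 1-based coordinate."""
        if not 0 <= offset < len(self.sequence):
            raise DomainError(f"offset {offset} outside amplicon of length {len(self)}")
        return self.genomic_start + offset

    def base_at(self, position: int) -> str:
        """Plus-strand base at a genomic coordinate."""
        return self.sequence[self.to_offset(position)]


@dataclass(frozen=True)
class GuideDesign:
    """A guide RNA and its genomic geometry.

    ``protospacer`` is written 5'->3' as the guide reads it (position 1 =
    PAM-distal end).  ``anchor`` is the genomic plus-strand coordinate of
    protospacer position 1; for a minus-strand guide successive protospacer
    positions map to *decreasing* plus-strand coordinates.  ``window`` is the
    inclusive protospacer-position range of ABE deaminase activity and
    ``target_position`` the intended edited adenine.
    """

    guide_id: str
    protospacer: str
    strand: str
    anchor: int
    target_position: int
    window: tuple[int, int] = (4, 7)
    contig: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "protospacer", self.protospacer.upper())
        if len(self.protospacer) != 20 or not set(self.protospacer) <= _DNA:
            raise ValidationError("protospacer must be a 20-nt ACGT string")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        lo, hi = self.window
        if not (1 <= lo <= hi <= 20):
            raise DomainError(f"window must lie within 1-20 with start <= end, got {self.window}")
        if not 1 <= self.target_position <= 20:
            raise DomainError(f"target_position must be in 1-20, got {self.target_position}")
        if self.protospacer[self.target_position - 1] != "A":
            raise ValidationError(
                "target_position must point at an adenine (an ABE edits A·T pairs); "
                f"protospacer position {self.target_position} is "
                f"{self.protospacer[self.target_position - 1]!r}"
            )

    @property
    def target_coordinate(self) -> int:
        return map_protospacer_position(self, self.target_position)[1]

    @property
    def intended_alt_plus(self) -> str:
        """Plus-strand base produced by the intended A->G edit.

        A->G on a minus-strand protospacer reads T->C on the plus strand.
        """
        return "G" if self.strand == "+" else "C"


@dataclass(frozen=True)
class CodonEdit:
    """A substitution expressed at codon level on the coding strand."""

    codon_before: str
    codon_after: str
    aa_before: str
    aa_after: str

    @property
    def synonymous(self) -> bool:
        return self.aa_before == self.aa_after


def map_protospacer_position(guide: GuideDesign, k: int) -> tuple[str, int]:
    """Genomic (contig, 1-based position) of protospacer position ``k``."""
    if not 1 <= k <= 20:
        raise DomainError(f"protospacer position must be in 1-20, got {k}")
    if guide.strand == "+":
        pos = guide.anchor + (k - 1)
    else:
        pos = guide.anchor - (k - 1)
    return guide.contig, pos


def protospacer_position_at(guide: GuideDesign, position: int) -> Optional[int]:
    """Inverse of :func:`map_protospacer_position`; None when off-protospacer."""
    if guide.strand == "+":
        k = position - guide.anchor + 1
    else:
        k = guide.anchor - position + 1
    return k if 1 <= k <= 20 else None


def enumerate_editable_positions(
    guide: GuideDesign, window: Optional[tuple[int, int]] = None
) -> list[int]:
    """Protospacer positions holding an adenine within the editing window,
    sorted ascending."""
    lo, hi = window if window is not None else guide.window
    if not (1 <= lo <= hi <= 20):
        raise DomainError(f"window must lie within 1-20 with start <= end, got {(lo, hi)}")
    return [k for k in range(lo, hi + 1) if guide.protospacer[k - 1] == "A"]


def adenine_run_length(guide: GuideDesign, k: int) -> int:
    """Length of the maximal run of consecutive adenines containing
    protospacer position ``k``.

    Adenine clusters matter for ABEs because every A in the window is a
    potential bystander: a long run around the target raises the chance of
    unintended co-edits.
    """
    if not 1 <= k <= 20:
        raise DomainError(f"protospacer position must be in 1-20, got {k}")
    if guide.protospacer[k - 1] != "A":
        raise DomainError(f"protospacer position {k} is {guide.protospacer[k - 1]!r}, not 'A'")
    lo = k
    while lo > 1 and guide.protospacer[lo - 2] == "A":
        lo -= 1
    hi = k
    while hi < 20 and guide.protospacer[hi] == "A":
        hi += 1
    return hi - lo + 1


def validate_guide_against_reference(guide: GuideDesign, ref: AmpliconReference) -> None:
    """Check that the protospacer matches the reference at its mapped
    coordinates (identity on the plus strand, complement on the minus)."""
    if guide.contig and ref.contig and guide.contig != ref.contig:
        raise ValidationError(f"guide contig {guide.contig!r} != reference contig {ref.contig!r}")
    for k in range(1, 21):
        _, pos = map_protospacer_position(guide, k)
        expected = guide.protospacer[k - 1]
        if guide.strand == "-":
            expected = expected.translate(COMPLEMENT)
        actual = ref.base_at(pos)  # raises DomainError when off the amplicon
        if actual != expected:
            raise ValidationError(
                f"guide {guide.guide_id} position {k}: reference has {actual!r} at "
                f"{ref.contig}:{pos}, protospacer implies {expected!r}"
            )


def classify_codon_edit(ref: AmpliconReference, position: int, alt: str) -> CodonEdit:
    """Classify the substitution ``position``->``alt`` (both given on the
    genomic plus strand) at codon level.

    The codon containing the position is reconstructed on the coding strand
    declared by ``ref.coding_frame``, the substitution applied, and both
    codons translated under the standard nuclear genetic code.
    """
    if ref.coding_frame is None:
        raise DomainError(f"reference {ref.name!r} carries no coding_frame annotation")
    alt = alt.upper()
    if alt not in _DNA:
        raise DomainError(f"alt base must be one of A/C/G/T, got {alt!r}")
    i = ref.to_offset(position)  # raises DomainError outside the amplicon
    frame = ref.coding_frame
    if frame.strand == "+":
        coding = ref.sequence
        j = i
        alt_coding = alt
    else:
        coding = revcomp(ref.sequence)
        j = len(ref.sequence) - 1 - i
        alt_coding = alt.translate(COMPLEMENT)
    start = j - ((j - frame.frame_offset) % 3)
    if start < 0 or start + 3 > len(coding):
        raise DomainError(
            f"codon containing {ref.contig}:{position} extends beyond the amplicon"
        )
    before = coding[start : start + 3]
    within = j - start
    after = before[:within] + alt_coding + before[within + 1 :]
    return CodonEdit(
        codon_before=before,
        codon_after=after,
        aa_before=str(Seq(before).translate()),
        aa_after=str(Seq(after).translate()),
    )
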