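"""Per-position base counts and cross-sample allele-frequency matrices.

This is the quantitative core of amplicon genotyping: every mapped fragment
contributes at most one base call per amplicon position (see
:mod:`ampliclone.align` for the mate-reconciliation rules), calls are tallied
into a pileup, and per-position *mutant allele frequencies* are derived from
the allele depths.  At the ~10,000x depth of an amplicon run this direct
allele-depth counting is the quantity of interest itself — no genotype
likelihood model intervenes between counts and frequencies.

Two frequency notions are exposed and kept distinct:

* ``non_ref_fraction(p)`` — fraction of calls at ``p`` that are not the
  reference base (deletions included); used for mosaicism scans.
* ``alt_fraction(p, alt)`` — fraction of calls equal to one specific
  alternate base; used to quantify the intended edit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .align import (
    DEFAULT_MAX_EDIT_FRAC,
    DEFAULT_QUALITY_FLOOR,
    FragmentCalls,
    align_to_amplicon,
    build_fragment_pileup,
)
from .errors import DomainError, EmptySampleError, ValidationError
from .reference import AmpliconReference, BASE_CODES
from .simulate import FastqRead

ReadSource = Union[str, Path, Iterable[tuple[str, str, str]]]

#: pileup column order; code 4 is a deletion call
PILEUP_COLUMNS = ("A", "C", "G", "T", "del")


@dataclass
class Pileup:
    """Per-position call counts over an amplicon.

    ``counts[p, c]`` is the number of fragments calling code ``c``
    (0-3 = A/C/G/T, 4 = deletion) at 0-based offset ``p``;
    ``insertion_starts[p]`` counts fragments with an insertion anchored at
    ``p``.  By construction ``counts.sum(axis=1) == depth`` everywhere.
    """

    counts: np.ndarray
    insertion_starts: np.ndarray

    @classmethod
    def empty(cls, length: int) -> "Pileup":
        return cls(np.zeros((length, 5), np.int64), np.zeros(length, np.int64))

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def add_fragment(self, calls: FragmentCalls) -> None:
        np.add.at(self.counts, (calls.positions, calls.codes), 1)
        last = self.insertion_starts.size - 1
        for off in calls.insertions:
            # a trailing insertion sits past the final base; anchor it there
            self.insertion_starts[min(off, last)] += 1


@dataclass
class SampleQuant:
    """One sample's pileup plus mapping bookkeeping."""

    sample_id: str
    ref_name: str
    contig: str
    genomic_start: int
    ref_codes: np.ndarray
    pileup: Pileup
    n_fragments: int
    n_mapped_fragments: int
    n_unmapped_reads: int

    @property
    def length(self) -> int:
        return self.ref_codes.size

    @property
    def positions(self) -> np.ndarray:
        """Genomic 1-based coordinates of the amplicon positions."""
        return self.genomic_start + np.arange(self.length)

    def depth_at(self, position: int) -> int:
        return int(self.pileup.depth[self._offset(position)])

    def _offset(self, position: int) -> int:
        off = position - self.genomic_start
        if not 0 <= off < self.length:
            raise DomainError(f"{self.contig}:{position} outside the quantified amplicon")
        return off

    def non_ref_fraction(self) -> pd.Series:
        """Per-position non-reference call fraction (NaN at zero depth)."""
        depth = self.pileup.depth.astype(float)
        ref_counts = self.pileup.counts[np.arange(self.length), self.ref_codes]
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(depth > 0, (depth - ref_counts) / depth, np.nan)
        return pd.Series(frac, index=self.positions, name=self.sample_id)

    def alt_fraction(self, position: int, alt: str) -> float:
        """Fraction of calls equal to ``alt`` at a genomic position."""
        off = self._offset(position)
        depth = self.pileup.depth[off]
        if depth == 0:
            return float("nan")
        return float(self.pileup.counts[off, BASE_CODES[alt.upper()]] / depth)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.pileup.counts, columns=list(PILEUP_COLUMNS))
        df.insert(0, "position", self.positions)
        df["ins"] = self.pileup.insertion_starts
        df["depth"] = self.pileup.depth
        df["non_ref_frac"] = self.non_ref_fraction().to_numpy()
        return df


def _iter_reads(source: ReadSource) -> Iterable[tuple[str, str, str]]:
    if isinstance(source, (str, Path)):
        from .io import iter_fastq

        return iter_fastq(source)
    return ((r.title, r.sequence, r.quality) if isinstance(r, FastqRead) else r for r in source)


def iter_fragment_calls(
    r1: ReadSource,
    r2: Optional[ReadSource],
    ref: AmpliconReference,
    quality_floor: int = DEFAULT_QUALITY_FLOOR,
    max_edit_frac: float = DEFAULT_MAX_EDIT_FRAC,
) -> Iterable[tuple[FragmentCalls, int]]:
    """Align read pairs and yield ``(fragment_calls, n_unmapped_mates)``.

    With ``r2=None`` the sample is treated as single-end.
    """
    reads1 = _iter_reads(r1)
    reads2 = _iter_reads(r2) if r2 is not None else None
    if reads2 is None:
        for title, seq, qual in reads1:
            a = align_to_amplicon(ref, seq, qual, read_id=title, max_edit_frac=max_edit_frac)
            calls = build_fragment_pileup(a, None, quality_floor)
            yield calls, (0 if a.mapped else 1)
        return
    for (t1, s1, q1), (t2, s2, q2) in zip(reads1, reads2, strict=True):
        a1 = align_to_amplicon(ref, s1, q1, read_id=t1, max_edit_frac=max_edit_frac)
        a2 = align_to_amplicon(
            ref, s2, q2, read_id=t2, max_edit_frac=max_edit_frac, orientation_hint="-"
        )
        calls = build_fragment_pileup(a1, a2, quality_floor)
        yield calls, (0 if a1.mapped else 1) + (0 if a2.mapped else 1)


def quantify_sample(
    r1: ReadSource,
    r2: Optional[ReadSource],
    ref: AmpliconReference,
    sample_id: str = "sample",
    quality_floor: int = DEFAULT_QUALITY_FLOOR,
    max_edit_frac: float = DEFAULT_MAX_EDIT_FRAC,
) -> SampleQuant:
    """Align a sample's reads and build its pileup.

    Raises :class:`EmptySampleError` when no fragment maps at all.
    """
    pileup = Pileup.empty(len(ref))
    n_frag = n_mapped = n_unmapped_reads = 0
    for calls, unmapped in iter_fragment_calls(
        r1, r2, ref, quality_floor=quality_floor, max_edit_frac=max_edit_frac
    ):
        n_frag += 1
        n_unmapped_reads += unmapped
        if calls.mapped and calls.positions.size:
            n_mapped += 1
            pileup.add_fragment(calls)
    if n_mapped == 0:
        raise EmptySampleError(
            f"sample {sample_id!r}: 0 of {n_frag} fragments mapped to {ref.name!r}"
        )
    return SampleQuant(
        sample_id=sample_id,
        ref_name=ref.name,
        contig=ref.contig,
        genomic_start=ref.genomic_start,
        ref_codes=ref.codes,
        pileup=pileup,
        n_fragments=n_frag,
        n_mapped_fragments=n_mapped,
        n_unmapped_reads=n_unmapped_reads,
    )


@dataclass
class AlleleFrequencyMatrix:
    """Samples x positions non-reference fractions with matched depths.

    ``values`` holds NaN where a position had zero depth — missing data is
    distinct from an observed frequency of zero.
    """

    values: pd.DataFrame
    depth: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.depth.index) or not self.values.columns.equals(
            self.depth.columns
        ):
            raise ValidationError("values and depth frames must share index and columns")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def positions(self) -> list[int]:
        return list(self.values.columns)


def aggregate_matrix(samples: Sequence[SampleQuant]) -> AlleleFrequencyMatrix:
    """Stack per-sample non-reference fractions into a cohort matrix.

    All samples must come from the same reference (name, contig, anchor and
    length); rows are ordered as given, columns by genomic position.
    """
    if not samples:
        raise ValidationError("cannot aggregate an empty sample list")
    key = (samples[0].ref_name, samples[0].contig, samples[0].genomic_start, samples[0].length)
    for s in samples[1:]:
        if (s.ref_name, s.contig, s.genomic_start, s.length) != key:
            raise ValidationError(
                f"sample {s.sample_id!r} quantified against a different reference"
            )
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate sample ids in cohort")
    values = pd.DataFrame(
        [s.non_ref_fraction().to_numpy() for s in samples],
        index=ids,
        columns=samples[0].positions,
    )
    depth = pd.DataFrame(
        [s.pileup.depth for s in samples], index=ids, columns=samples[0].positions
    )
    return AlleleFrequencyMatrix(values=values, depth=depth)
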