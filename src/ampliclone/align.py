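"""Adapter trimming, semi-global alignment and fragment-level base calls.

Reads from an amplicon assay come from one known short sequence, so instead
of a genome mapper each read is aligned directly to the amplicon with a
semi-global Levenshtein alignment (free end-gaps on the reference, unit
mismatch and gap costs; the `edlib` C library does the dynamic programming).
Both orientations are tried and the better one kept, so R1/R2 need no prior
orientation bookkeeping.  A read is flagged unmapped — never silently
dropped — when its edit distance exceeds 20 % of its length.

Mates of a fragment are reconciled before counting: where they overlap,
agreeing bases are counted once and disagreements are masked, and bases
below the quality floor are masked, so a fragment contributes at most one
call per amplicon position.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

import edlib
import numpy as np

from .reference import AmpliconReference, encode, revcomp

DEFAULT_MAX_EDIT_FRAC = 0.2
DEFAULT_QUALITY_FLOOR = 20

_CIGAR_RE = re.compile(r"(\d+)([=XID])")


@dataclass
class ReadAlignment:
    """A read placed on the amplicon.

    ``amplicon_offset`` is the 0-based offset of the first aligned reference
    base; ``strand`` records the orientation in which the read matched
    ('-' means the stored ``sequence``/``quality`` are the reverse
    complement / reversal of the input).  ``contiguous`` is True when the
    alignment contains no indels, i.e. read index i maps to reference index
    ``amplicon_offset + i``.
    """

    read_id: str
    amplicon_offset: int
    edit_distance: int
    mapped: bool
    strand: str
    cigar: str
    sequence: str
    quality: Optional[str] = None

    @property
    def contiguous(self) -> bool:
        return "I" not in self.cigar and "D" not in self.cigar

    @property
    def ref_end(self) -> int:
        """0-based exclusive reference offset past the last aligned base."""
        span = sum(n for n, op in _iter_cigar(self.cigar) if op in "=XD")
        return self.amplicon_offset + span

    def aligned_pairs(self) -> list[tuple[Optional[int], Optional[int]]]:
        """(read_index, amplicon_index) pairs; None marks a gap on that side.

        Monotone increasing in both coordinates.
        """
        pairs: list[tuple[Optional[int], Optional[int]]] = []
        ri, ai = 0, self.amplicon_offset
        for n, op in _iter_cigar(self.cigar):
            if op in "=X":
                for _ in range(n):
                    pairs.append((ri, ai))
                    ri += 1
                    ai += 1
            elif op == "I":  # extra read base: insertion relative to the amplicon
                for _ in range(n):
                    pairs.append((ri, None))
                    ri += 1
            else:  # 'D': amplicon base skipped by the read: deletion
                for _ in range(n):
                    pairs.append((None, ai))
                    ai += 1
        return pairs


def _iter_cigar(cigar: str) -> Iterator[tuple[int, str]]:
    for m in _CIGAR_RE.finditer(cigar):
        yield int(m.group(1)), m.group(2)


def trim_adapter(sequence: str, adapter: str, max_mismatch_frac: float = 0.1,
                 min_match: int = 3) -> str:
    """Remove a 3' adapter from a read sequence.

    Scans every suffix start position for a prefix match of the adapter of
    length >= ``min_match`` with at most ``max_mismatch_frac`` mismatches,
    and cuts at the best match (lowest mismatch rate; ties broken towards
    the longest, i.e. earliest, match).  No-op when nothing qualifies.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    best: Optional[tuple[float, int]] = None
    n = len(sequence)
    for start in range(n - min_match + 1):
        m = min(len(adapter), n - start)
        mism = sum(1 for a, b in zip(sequence[start : start + m], adapter[:m]) if a != b)
        if mism <= max_mismatch_frac * m:
            rate = mism / m
            if best is None or rate < best[0]:
                best = (rate, start)
    return sequence if best is None else sequence[: best[1]]


def align_to_amplicon(
    ref: AmpliconReference,
    sequence: str,
    quality: Optional[str] = None,
    read_id: str = "",
    max_edit_frac: float = DEFAULT_MAX_EDIT_FRAC,
    try_reverse: bool = True,
    orientation_hint: str = "+",
) -> ReadAlignment:
    """Semi-global alignment of one read against the amplicon.

    Tries the read as given and (unless ``try_reverse=False``) reverse
    complemented, keeping the orientation with the smaller edit distance.
    ``orientation_hint`` picks which orientation to try first (a
    near-perfect first hit skips the second alignment; R2 of a fragment is
    expected on '-').  ``mapped`` is False when the best distance exceeds
    ``max_edit_frac * len(sequence)``.
    """
    if orientation_hint == "-" and try_reverse:
        first_seq, first_strand = revcomp(sequence), "-"
    else:
        first_seq, first_strand = sequence, "+"
    first = edlib.align(first_seq, ref.sequence, mode="HW", task="path")
    best, best_seq, strand = first, first_seq, first_strand
    # a near-perfect hit cannot be beaten by the other orientation
    if try_reverse and first["editDistance"] > 2:
        other_seq = revcomp(first_seq)
        other = edlib.align(other_seq, ref.sequence, mode="HW", task="path")
        if other["editDistance"] < first["editDistance"]:
            best, best_seq = other, other_seq
            strand = "-" if first_strand == "+" else "+"
    if strand == "-":
        quality = quality[::-1] if quality is not None else None
    sequence = best_seq
    dist = best["editDistance"]
    start = best["locations"][0][0] if best["locations"] else 0
    cigar = best["cigar"] or ""
    # Unit-cost paths are ambiguous: a pair of nearby substitutions can be
    # rendered as an equal-cost balanced D/I pair, which would erase calls
    # at intervening positions.  Prefer the substitution-only interpretation
    # whenever one of equal (or better) cost exists near the placement.
    if "I" in cigar and "D" in cigar:
        n = len(sequence)
        query = encode(sequence)
        best_ham, best_start = None, start
        for s in (start - 1, start, start + 1):
            if s < 0 or s + n > len(ref.sequence):
                continue
            ham = int(np.count_nonzero(query != ref.codes[s : s + n]))
            if best_ham is None or ham < best_ham:
                best_ham, best_start = ham, s
        if best_ham is not None and best_ham <= dist:
            dist, start = best_ham, best_start
            mism = query != ref.codes[best_start : best_start + n]
            ops: list[str] = []
            run_op, run_len = None, 0
            for is_x in mism:
                op = "X" if is_x else "="
                if op == run_op:
                    run_len += 1
                else:
                    if run_op is not None:
                        ops.append(f"{run_len}{run_op}")
                    run_op, run_len = op, 1
            ops.append(f"{run_len}{run_op}")
            cigar = "".join(ops)
    return ReadAlignment(
        read_id=read_id,
        amplicon_offset=start,
        edit_distance=dist,
        mapped=dist <= max_edit_frac * len(sequence),
        strand=strand,
        cigar=cigar,
        sequence=sequence,
        quality=quality,
    )


@dataclass
class FragmentCalls:
    """Reconciled base calls of one fragment.

    ``positions`` are 0-based amplicon offsets, ``codes`` the base codes
    (0-3 = A/C/G/T, 4 = deletion); positions masked by quality or mate
    disagreement are simply absent.  ``insertions`` lists amplicon offsets
    at which the fragment carries an insertion start.
    """

    positions: np.ndarray
    codes: np.ndarray
    insertions: tuple[int, ...] = ()
    mapped: bool = True


def _read_call_arrays(
    aln: ReadAlignment, quality_floor: int
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Per-read (positions, codes, insertion anchors) after quality masking."""
    codes = encode(aln.sequence)
    qual: Optional[np.ndarray] = None
    if aln.quality is not None:
        qual = np.frombuffer(aln.quality.encode("ascii"), dtype=np.uint8).astype(np.int32) - 33
    if aln.contiguous:
        positions = aln.amplicon_offset + np.arange(codes.size, dtype=np.int64)
        if qual is not None and qual.min() < quality_floor:
            ok = qual >= quality_floor
            return positions[ok], codes[ok], []
        return positions, codes, []
    pos_l: list[int] = []
    code_l: list[int] = []
    ins: list[int] = []
    ri, ai = 0, aln.amplicon_offset
    for n, op in _iter_cigar(aln.cigar):
        if op in "=X":
            for _ in range(n):
                if qual is None or qual[ri] >= quality_floor:
                    pos_l.append(ai)
                    code_l.append(int(codes[ri]))
                ri += 1
                ai += 1
        elif op == "I":  # insertion anchored at the reference base it precedes
            ins.append(ai)
            ri += n
        else:  # 'D': the read skips reference bases -> deletion calls
            for _ in range(n):
                pos_l.append(ai)
                code_l.append(4)
                ai += 1
    return np.array(pos_l, dtype=np.int64), np.array(code_l, dtype=np.uint8), sorted(set(ins))


def build_fragment_pileup(
    r1: ReadAlignment,
    r2: Optional[ReadAlignment],
    quality_floor: int = DEFAULT_QUALITY_FLOOR,
) -> FragmentCalls:
    """Merge the calls of a fragment's two mates.

    Positions covered by one mate contribute that mate's call; where mates
    overlap, agreeing calls are counted once and disagreements masked.
    """
    mates = [m for m in (r1, r2) if m is not None and m.mapped]
    if not mates:
        return FragmentCalls(np.empty(0, np.int64), np.empty(0, np.uint8), (), mapped=False)
    arrays = [_read_call_arrays(m, quality_floor) for m in mates]
    if len(arrays) == 1:
        p, c, ins = arrays[0]
        return FragmentCalls(p, c, tuple(ins))
    (p1, c1, i1), (p2, c2, i2) = arrays
    overlap_possible = p1.size and p2.size and p1.max() >= p2.min() and p2.max() >= p1.min()
    if overlap_possible:
        common, idx1, idx2 = np.intersect1d(p1, p2, return_indices=True)
    if overlap_possible and common.size:
        agree = c1[idx1] == c2[idx2]
        keep1 = np.ones(p1.size, bool)
        keep1[idx1[~agree]] = False  # disagreement: mask on both sides
        keep2 = np.ones(p2.size, bool)
        keep2[idx2] = False  # overlap counted once (via mate 1 where agreeing)
        p = np.concatenate([p1[keep1], p2[keep2]])
        c = np.concatenate([c1[keep1], c2[keep2]])
    else:
        p = np.concatenate([p1, p2])
        c = np.concatenate([c1, c2])
    return FragmentCalls(p, c, tuple(sorted(set(i1) | set(i2))))
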