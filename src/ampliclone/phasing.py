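"""Read-backed phasing of an induced edit against a germline variant.

A clone edited on one chromosome can be phased against a nearby germline
heterozygous SNV: every sequenced fragment that covers both sites reports
one joint haplotype, and with sites ~238 bp apart on a 363 bp product each
150 bp mate covers one site, so the phasing unit is the *fragment* (read
pair), not the single read.  The 2x2 joint-allele table then answers two
questions at once: which germline allele the edit travels with (cis/trans)
and whether the colony is monoclonal — a true single-cell clone shows a
balanced germline allele ratio and a near-pure phase signal, whereas mixed
colonies leak counts into the off-phase cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .errors import NoPhaseError, ValidationError

PHASE_CIS_1 = "cis_with_allele_1"
PHASE_CIS_2 = "cis_with_allele_2"
PHASE_AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class EditSite:
    """The induced substitution: genomic position, reference and edited base."""

    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValidationError("edit site ref and alt must differ")


@dataclass(frozen=True)
class GermlineSite:
    """The heterozygous germline marker variant (e.g. an rsID SNV)."""

    position: int
    allele1: str
    allele2: str

    def __post_init__(self) -> None:
        if self.allele1 == self.allele2:
            raise ValidationError("germline alleles must differ")


@dataclass(frozen=True)
class PhasingSites:
    """The two sites jointly genotyped per fragment."""

    edit_site: EditSite
    germline_site: GermlineSite

    def __post_init__(self) -> None:
        if self.edit_site.position == self.germline_site.position:
            raise ValidationError("edit and germline sites must be distinct")

    @property
    def expected_distance(self) -> int:
        """Distance in bp between the two sites."""
        return abs(self.edit_site.position - self.germline_site.position)


@dataclass
class PhasingResult:
    """Joint haplotype counts and the calls derived from them.

    ``joint_counts[i, j]`` counts fragments with edit allele i (0 = ref,
    1 = alt) and germline allele j (0 = allele_1, 1 = allele_2).
    """

    joint_counts: np.ndarray
    uninformative_fragments: int
    phase_call: str
    purity: float
    germline_balance: float
    monoclonal: Optional[bool] = None
    diagnostics: tuple[str, ...] = ()

    @property
    def informative_fragments(self) -> int:
        return int(self.joint_counts.sum())

    @property
    def edit_fraction(self) -> float:
        n = self.informative_fragments
        return float(self.joint_counts[1].sum() / n) if n else float("nan")


def count_joint_alleles(
    fragment_calls: Iterable[Mapping[int, str]],
    sites: PhasingSites,
) -> tuple[np.ndarray, int]:
    """Tally per-fragment joint alleles into a 2x2 table.

    ``fragment_calls`` yields one mapping per fragment from genomic position
    to the (unmasked) base called there.  A fragment is informative only if
    it calls both sites and each call matches one of the expected alleles;
    anything else (single-site coverage, masked overlap conflict, a third
    base from a sequencing error) is tallied as uninformative.

    Returns ``(table, n_uninformative)``.
    """
    e, g = sites.edit_site, sites.germline_site
    table = np.zeros((2, 2), dtype=np.int64)
    uninformative = 0
    for calls in fragment_calls:
        be = calls.get(e.position)
        bg = calls.get(g.position)
        if be == e.ref:
            i = 0
        elif be == e.alt:
            i = 1
        else:
            uninformative += 1
            continue
        if bg == g.allele1:
            j = 0
        elif bg == g.allele2:
            j = 1
        else:
            uninformative += 1
            continue
        table[i, j] += 1
    return table, uninformative


def call_phase(
    table: np.ndarray,
    min_fragments: int = 100,
    min_purity: float = 0.9,
) -> tuple[str, float]:
    """Call cis/trans from the joint table.

    Among fragments carrying the edited allele, ``purity`` is the majority
    germline-allele share.  The call is ``ambiguous`` when fewer than
    ``min_fragments`` edited fragments are available or purity falls below
    ``min_purity`` — ambiguity is a value, not an error.
    """
    table = np.asarray(table)
    alt_row = table[1]
    n_alt = int(alt_row.sum())
    if n_alt == 0:
        return PHASE_AMBIGUOUS, 0.5
    purity = float(alt_row.max() / n_alt)
    if n_alt < min_fragments or purity < min_purity:
        return PHASE_AMBIGUOUS, purity
    call = PHASE_CIS_1 if alt_row[0] >= alt_row[1] else PHASE_CIS_2
    return call, purity


def assess_monoclonality(
    result: PhasingResult,
    balance_tolerance: float = 0.15,
    min_purity: float = 0.9,
    edit_fraction_band: tuple[float, float] = (0.30, 0.65),
) -> tuple[bool, tuple[str, ...]]:
    """Judge whether the colony descends from a single cell.

    A monoclonal heterozygously edited colony shows (i) a germline allele
    balance near 50 % (template from two chromosomes in equal amounts),
    (ii) a pure phase signal (the edit confined to one allele), and
    (iii) an edit fraction inside the expected zygosity band.  Each failed
    criterion is named in the returned diagnostics.
    """
    diagnostics: list[str] = []
    if abs(result.germline_balance - 0.5) > balance_tolerance:
        diagnostics.append("germline_imbalance")
    if result.purity < min_purity:
        diagnostics.append("low_phase_purity")
    lo, hi = edit_fraction_band
    ef = result.edit_fraction
    if not (lo <= ef < hi):  # NaN fails the comparison and is flagged too
        diagnostics.append("edit_fraction_outside_band")
    return (len(diagnostics) == 0), tuple(diagnostics)


def summarize_phasing(
    table: np.ndarray,
    uninformative: int,
    min_fragments: int = 100,
    min_purity: float = 0.9,
    balance_tolerance: float = 0.15,
    edit_fraction_band: tuple[float, float] = (0.30, 0.65),
) -> PhasingResult:
    """Assemble a :class:`PhasingResult` from a joint table."""
    table = np.asarray(table, dtype=np.int64)
    n = int(table.sum())
    if n == 0:
        raise NoPhaseError("zero informative fragments: cannot phase")
    balance = float(table[:, 0].sum() / n)
    call, purity = call_phase(table, min_fragments=min_fragments, min_purity=min_purity)
    result = PhasingResult(
        joint_counts=table,
        uninformative_fragments=uninformative,
        phase_call=call,
        purity=purity,
        germline_balance=balance,
    )
    mono, diag = assess_monoclonality(
        result,
        balance_tolerance=balance_tolerance,
        min_purity=min_purity,
        edit_fraction_band=edit_fraction_band,
    )
    result.monoclonal = mono
    result.diagnostics = diag
    return result
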