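"""Clone triage: editing efficiency, zygosity bands, mosaicism, bystanders.

Screening a base-editing experiment means sorting each clone into an
actionable category from its target-edit allele frequency f:

==============================  ==========================
f < detect (2 %)                unedited
detect <= f < het (30 %)        low_fraction_edited
het <= f < homozygous (65 %)    heterozygous_candidate
f >= homozygous                 potential_homozygous
==============================  ==========================

All comparisons are inclusive on the lower edge (">= 2 %" style).  On top
of the band, a clone is flagged *mosaic* when any unintended allele — any
substitution, deletion or insertion other than the intended edit — reaches
the mosaic threshold (5 %); unintended alleles above the noise floor
(0.5 %) are listed even when they do not trip the flag.  Bystander edits
(the intended base change at a non-target editable window position) are
reported separately per protospacer position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .errors import DomainError, NoCallError, ValidationError
from .quantify import AlleleFrequencyMatrix, SampleQuant
from .reference import (
    BASE_CODES,
    CODE_BASES,
    GuideDesign,
    enumerate_editable_positions,
    map_protospacer_position,
)

CATEGORY_UNEDITED = "unedited"
CATEGORY_LOW = "low_fraction_edited"
CATEGORY_HET = "heterozygous_candidate"
CATEGORY_HOM = "potential_homozygous"
CATEGORIES = (CATEGORY_UNEDITED, CATEGORY_LOW, CATEGORY_HET, CATEGORY_HOM)


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds of the clone classifier (all on allele-fraction scale).

    ``noise_floor`` separates sequencing noise from true subclonal alleles
    when listing mosaic alleles; it is an assay calibration, not a band.
    """

    detect_threshold: float = 0.02
    het_threshold: float = 0.30
    homozygous_threshold: float = 0.65
    mosaic_allele_threshold: float = 0.05
    noise_floor: float = 0.005

    def __post_init__(self) -> None:
        if not (
            0.0
            < self.noise_floor
            < self.detect_threshold
            < self.het_threshold
            < self.homozygous_threshold
            <= 1.0
        ):
            raise ValidationError(
                "require 0 < noise_floor < detect < het < homozygous <= 1, got "
                f"{self}"
            )

    def category(self, f: float) -> str:
        """Zygosity band of a target-edit fraction (total on [0, 1])."""
        if f < self.detect_threshold:
            return CATEGORY_UNEDITED
        if f < self.het_threshold:
            return CATEGORY_LOW
        if f < self.homozygous_threshold:
            return CATEGORY_HET
        return CATEGORY_HOM


@dataclass
class CloneCall:
    """Genotyping verdict for one clone."""

    sample_id: str
    target_position: int  # genomic coordinate of the intended edit
    target_edit_fraction: float
    target_depth: int
    category: str
    mosaic: bool
    mosaic_alleles: tuple[tuple[int, str, float], ...]  # (position, allele, fraction)
    bystander_edits: tuple[tuple[int, float], ...]  # (protospacer position, fraction)


def classify_clone(
    quant: SampleQuant,
    guide: GuideDesign,
    cfg: ClassifierConfig = ClassifierConfig(),
) -> CloneCall:
    """Classify one quantified clone against its guide design.

    Raises :class:`NoCallError` when the target position has zero depth —
    an uncovered target is a failed assay, not an unedited clone.
    """
    _, target = map_protospacer_position(guide, guide.target_position)
    intended_alt = guide.intended_alt_plus
    if quant.depth_at(target) == 0:
        raise NoCallError(f"sample {quant.sample_id!r}: zero depth at target {target}")
    f = quant.alt_fraction(target, intended_alt)

    counts = quant.pileup.counts
    depth = quant.pileup.depth.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(depth[:, None] > 0, counts / np.maximum(depth, 1)[:, None], 0.0)
        ins_frac = np.where(depth > 0, quant.pileup.insertion_starts / np.maximum(depth, 1), 0.0)

    target_off = target - quant.genomic_start
    mosaic_alleles: list[tuple[int, str, float]] = []
    for off, code in zip(*np.nonzero(frac >= cfg.noise_floor)):
        if code == quant.ref_codes[off]:
            continue
        allele = "del" if code == 4 else CODE_BASES[code]
        if off == target_off and allele == intended_alt:
            continue  # the intended edit is not a mosaic allele
        mosaic_alleles.append((int(quant.genomic_start + off), allele, float(frac[off, code])))
    for off in np.flatnonzero(ins_frac >= cfg.noise_floor):
        mosaic_alleles.append((int(quant.genomic_start + off), "ins", float(ins_frac[off])))
    mosaic_alleles.sort(key=lambda t: (-t[2], t[0]))
    mosaic = any(fr >= cfg.mosaic_allele_threshold for _, _, fr in mosaic_alleles)

    bystanders: list[tuple[int, float]] = []
    for k in enumerate_editable_positions(guide):
        if k == guide.target_position:
            continue
        _, pos = map_protospacer_position(guide, k)
        if not quant.genomic_start <= pos < quant.genomic_start + quant.length:
            continue
        bf = quant.alt_fraction(pos, intended_alt)
        if bf >= cfg.detect_threshold:
            bystanders.append((k, float(bf)))

    return CloneCall(
        sample_id=quant.sample_id,
        target_position=target,
        target_edit_fraction=float(f),
        target_depth=quant.depth_at(target),
        category=cfg.category(float(f)),
        mosaic=mosaic,
        mosaic_alleles=tuple(mosaic_alleles),
        bystander_edits=tuple(bystanders),
    )


def summarize_efficiency(
    calls_or_counts: Union[Sequence[CloneCall], tuple[int, int]],
    threshold: float = 0.02,
) -> int:
    """Editing efficiency as an integer percentage, rounded half-up.

    Accepts either ``(positives, total)`` counts or a sequence of clone
    calls, in which case positives are clones whose target-edit fraction
    reaches ``threshold`` (inclusive).
    """
    if (
        isinstance(calls_or_counts, tuple)
        and len(calls_or_counts) == 2
        and all(isinstance(x, (int, np.integer)) for x in calls_or_counts)
    ):
        positives, total = calls_or_counts
    else:
        calls = list(calls_or_counts)
        positives = sum(1 for c in calls if c.target_edit_fraction >= threshold)
        total = len(calls)
    if total < 1:
        raise DomainError("total must be >= 1")
    if not 0 <= positives <= total:
        raise DomainError(f"need 0 <= positives <= total, got {positives}/{total}")
    return int(np.floor(100.0 * positives / total + 0.5))


def positional_positivity_profile(
    matrix: AlleleFrequencyMatrix, threshold: float = 0.02
) -> pd.Series:
    """Per-position fraction of samples at or above ``threshold``.

    This is the cohort-level profile plotted to locate the editing window:
    a peak at the target column, a shoulder at bystander positions.
    Positions with missing data (zero depth) count as not positive; the
    denominator is always the full sample count.
    """
    if not len(matrix.values):
        raise ValidationError("matrix is empty")
    return (matrix.values >= threshold).mean(axis=0)
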