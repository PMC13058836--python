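"""Synthetic paired-end amplicon reads for clones with known haplotype mixtures.

Amplicon sequencing of an edited cell clone produces reads from a single
defined PCR product; the clone itself may be a *mixture* of haplotypes
(wild type, the intended edit, bystander edits, subclonal contaminants),
each contributing fragments in proportion to its cell fraction.  The
simulator draws each fragment from a haplotype with probability equal to
its weight, slices fixed-length paired 150 bp reads off the two fragment
ends, and injects independent per-base substitution errors — the error
model appropriate for an Illumina amplicon run once indels are not part of
the editing chemistry (an optional per-fragment deletion rate exists for
robustness tests).

Read names carry the ground-truth haplotype label in the FASTQ comment
field so downstream estimates can be checked against an oracle recount.
Identical inputs and seed produce byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .errors import ValidationError
from .reference import AmpliconReference, decode, encode
from .phasing import PhasingSites

WEIGHT_TOL = 1e-9


class FastqRead(NamedTuple):
    """One FASTQ record; ``title`` is the full header line minus '@'."""

    title: str
    sequence: str
    quality: str


@dataclass(frozen=True)
class Haplotype:
    """One haplotype of a clone: substitutions relative to the reference
    plus the fraction of cells (hence fragments) carrying it.

    ``substitutions`` are (1-based amplicon position, alt base) pairs.
    """

    label: str
    substitutions: tuple[tuple[int, str], ...] = ()
    weight: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "substitutions",
            tuple((int(p), b.upper()) for p, b in self.substitutions),
        )
        if not 0.0 <= self.weight <= 1.0:
            raise ValidationError(f"haplotype weight must be in [0, 1], got {self.weight}")


@dataclass(frozen=True)
class SimConfig:
    """Sequencing-run parameters.

    Defaults follow the study conditions this package models: paired-end
    150 bp reads off a 363 bp product, ~10,000 fragments per clone for
    quantification, Q30 bases with a 1e-3 per-base substitution error.
    """

    depth: int = 10_000
    read_length: int = 150
    fragment_length: int = 363
    fragment_start: int = 0
    per_base_error: float = 0.001
    base_quality: int = 30
    indel_rate: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValidationError("depth must be >= 1")
        if not 0 < self.read_length <= self.fragment_length:
            raise ValidationError("require 0 < read_length <= fragment_length")
        if not 0.0 <= self.per_base_error < 0.25:
            raise ValidationError("per_base_error must lie in [0, 0.25)")
        if not 0.0 <= self.indel_rate < 1.0:
            raise ValidationError("indel_rate must lie in [0, 1)")


@dataclass(frozen=True)
class CloneSpec:
    """A named clone: its haplotype mixture and the guide it was edited with."""

    sample_id: str
    haplotypes: tuple[Haplotype, ...]
    guide_id: str = ""


@dataclass
class SimulatedClone:
    """Paired reads plus the ground-truth manifest of one simulated clone."""

    clone_id: str
    r1: list[FastqRead]
    r2: list[FastqRead]
    haplotype_counts: dict[str, int]
    config: SimConfig

    def truth_fraction(self, label: str) -> float:
        """Realised fragment fraction of a haplotype (the binomial draw,
        not the nominal weight)."""
        return self.haplotype_counts.get(label, 0) / self.config.depth

    def manifest(self) -> dict:
        return {
            "clone_id": self.clone_id,
            "depth": self.config.depth,
            "haplotype_counts": dict(self.haplotype_counts),
            "per_base_error": self.config.per_base_error,
            "read_length": self.config.read_length,
            "fragment_length": self.config.fragment_length,
            "fragment_start": self.config.fragment_start,
        }


def haplotype_sequence(ref: AmpliconReference, hap: Haplotype) -> str:
    """Full amplicon sequence of a haplotype; validates its substitutions."""
    seq = list(ref.sequence)
    for pos, alt in hap.substitutions:
        if not 1 <= pos <= len(seq):
            raise ValidationError(
                f"haplotype {hap.label!r}: position {pos} outside amplicon of length {len(seq)}"
            )
        if alt not in "ACGT":
            raise ValidationError(f"haplotype {hap.label!r}: alt base {alt!r} invalid")
        if seq[pos - 1] == alt:
            raise ValidationError(
                f"haplotype {hap.label!r}: alt at position {pos} equals the reference base {alt!r}"
            )
        seq[pos - 1] = alt
    return "".join(seq)


def _validate_haplotypes(ref: AmpliconReference, haplotypes: Sequence[Haplotype]) -> None:
    if not haplotypes:
        raise ValidationError("need at least one haplotype")
    total = sum(h.weight for h in haplotypes)
    if abs(total - 1.0) > WEIGHT_TOL:
        raise ValidationError(f"haplotype weights must sum to 1, got {total!r}")
    labels = [h.label for h in haplotypes]
    if len(set(labels)) != len(labels):
        raise ValidationError("haplotype labels must be unique within a clone")


def simulate_clone(
    ref: AmpliconReference,
    haplotypes: Sequence[Haplotype],
    cfg: SimConfig,
    clone_id: str = "clone",
) -> SimulatedClone:
    """Simulate one clone's paired-end FASTQ.

    Each of ``cfg.depth`` fragments is drawn from a haplotype with
    probability equal to its weight; R1 is the fragment 5' prefix of
    ``read_length``, R2 the reverse complement of the 3' suffix.  Per-base
    substitution errors occur independently at ``per_base_error``, uniform
    over the three alternative bases.
    """
    _validate_haplotypes(ref, haplotypes)
    flen, rlen = cfg.fragment_length, cfg.read_length
    if cfg.fragment_start < 0 or cfg.fragment_start + flen > len(ref):
        raise ValidationError(
            f"fragment [{cfg.fragment_start}, {cfg.fragment_start + flen}) outside "
            f"amplicon of length {len(ref)}"
        )
    rng = np.random.default_rng(cfg.seed)

    hap_codes = np.stack(
        [
            encode(haplotype_sequence(ref, h))[cfg.fragment_start : cfg.fragment_start + flen]
            for h in haplotypes
        ]
    )
    weights = np.array([h.weight for h in haplotypes], dtype=float)
    weights = weights / weights.sum()  # renormalise away the <=1e-9 slack

    hap_idx = rng.choice(len(haplotypes), size=cfg.depth, p=weights)
    frags = hap_codes[hap_idx].copy()  # depth x flen uint8

    if cfg.per_base_error > 0:
        err = rng.random(frags.shape) < cfg.per_base_error
        n_err = int(err.sum())
        if n_err:
            frags[err] = (frags[err] + rng.integers(1, 4, n_err, dtype=np.uint8)) % 4

    if cfg.indel_rate > 0:
        hit = np.flatnonzero(rng.random(cfg.depth) < cfg.indel_rate)
        del_pos = rng.integers(0, flen, hit.size)
    else:
        hit, del_pos = np.array([], dtype=int), np.array([], dtype=int)
    hit_set = dict(zip(hit.tolist(), del_pos.tolist()))

    qual = chr(cfg.base_quality + 33) * rlen
    labels = [h.label for h in haplotypes]
    r1: list[FastqRead] = []
    r2: list[FastqRead] = []
    counts = {lab: 0 for lab in labels}
    for i in range(cfg.depth):
        lab = labels[hap_idx[i]]
        counts[lab] += 1
        row = frags[i]
        if i in hit_set:  # rare robustness path: single-base deletion
            row = np.delete(row, hit_set[i])
        frag = decode(row)
        title = f"{clone_id}:{i} hap={lab}"
        r1.append(FastqRead(title, frag[:rlen], qual[: min(rlen, len(frag))]))
        tail = frag[-rlen:]
        r2.append(
            FastqRead(title, tail.translate(_RC_TABLE)[::-1], qual[: len(tail)])
        )
    return SimulatedClone(clone_id, r1, r2, counts, cfg)


_RC_TABLE = str.maketrans("ACGT", "TGCA")


def heterozygous_phased_haplotypes(
    ref: AmpliconReference,
    sites: PhasingSites,
    phase: str,
    edited_fraction: float = 1.0,
    germline_balance: float = 0.5,
) -> list[Haplotype]:
    """Haplotypes of a clone heterozygous for the induced edit.

    The clone carries two chromosomes marked by the germline alleles; the
    edit sits on the chromosome carrying ``allele_1`` when ``phase='cis'``
    (cis is defined relative to allele_1) and on the other for ``'trans'``.
    ``edited_fraction`` is the fraction of the edited chromosome's fragments
    that actually carry the edit (1.0 = clean heterozygous clone; lower
    values model mosaic editing).  ``germline_balance`` is the fragment
    share of the allele_1 chromosome (0.5 = balanced template input).
    """
    if phase not in ("cis", "trans"):
        raise ValidationError(f"phase must be 'cis' or 'trans', got {phase!r}")
    e_pos = ref.to_offset(sites.edit_site.position) + 1
    g_pos = ref.to_offset(sites.germline_site.position) + 1
    if ref.sequence[e_pos - 1] != sites.edit_site.ref:
        raise ValidationError("edit site ref base does not match the amplicon")
    edit_sub = (e_pos, sites.edit_site.alt)
    g_ref = ref.sequence[g_pos - 1]
    a1, a2 = sites.germline_site.allele1, sites.germline_site.allele2
    if g_ref not in (a1, a2):
        raise ValidationError("neither germline allele matches the amplicon base")
    subs_a1 = () if a1 == g_ref else ((g_pos, a1),)
    subs_a2 = () if a2 == g_ref else ((g_pos, a2),)
    w1, w2 = germline_balance, 1.0 - germline_balance
    edited_subs = subs_a1 if phase == "cis" else subs_a2
    other_subs = subs_a2 if phase == "cis" else subs_a1
    haps = [
        Haplotype("edited", edited_subs + (edit_sub,), (w1 if phase == "cis" else w2) * edited_fraction),
        Haplotype("unedited_same", edited_subs, (w1 if phase == "cis" else w2) * (1 - edited_fraction)),
        Haplotype("other", other_subs, w2 if phase == "cis" else w1),
    ]
    return [h for h in haps if h.weight > 0]


def simulate_phased_clone(
    ref: AmpliconReference,
    sites: PhasingSites,
    phase: str,
    cfg: SimConfig,
    clone_id: str = "phased_clone",
    edited_fraction: float = 1.0,
    germline_balance: float = 0.5,
) -> SimulatedClone:
    """Simulate a clone for the two-site phasing assay.

    Both sites must fall inside the simulated fragment, otherwise the assay
    is geometrically impossible and a :class:`ValidationError` is raised.
    """
    span_lo = cfg.fragment_start + 1
    span_hi = cfg.fragment_start + cfg.fragment_length
    for site_pos in (sites.edit_site.position, sites.germline_site.position):
        off = ref.to_offset(site_pos) + 1
        if not span_lo <= off <= span_hi:
            raise ValidationError(
                f"site at {ref.contig}:{site_pos} not covered by the simulated fragment"
            )
    haps = heterozygous_phased_haplotypes(
        ref, sites, phase, edited_fraction=edited_fraction, germline_balance=germline_balance
    )
    return simulate_clone(ref, haps, cfg, clone_id=clone_id)
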