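"""Built-in design for the AUTS2 exon-10 base-editing assay.

The assay this package models edits adenines in exon 10 of human *AUTS2*
(chr7, hg38) with an adenine base editor, genotypes clones by amplicon NGS
and phases the induced substitution against the germline SNV rs3829006.
Two guides target the locus:

* ``N044`` (plus strand): protospacer ``CAAAAGTTGACCCATTCTAC``; the intended
  edit is the adenine at protospacer position 5 (chr7:70768044), the third
  base of an AAA lysine codon, so A->G is synonymous (AAA->AAG).  Positions
  2-5 form a four-adenine run, making position 4 (chr7:70768043) the main
  bystander.
* ``N068`` (minus strand): protospacer ``TCACACTGTGCCGGTAGAAT``; its target
  adenine at protospacer position 5 sits opposite chr7:70768068, so the edit
  reads T->C on the plus strand and is again synonymous (AGT->AGC serine).

No public read archive accompanies the assay, so the module reconstructs a
*synthetic* 363 bp surrogate amplicon: the 33 bp chr7:70768040-70768072 core
is derived from the two protospacers (which overlap consistently and pin
every base), the germline G of rs3829006 is placed at chr7:70768282, the
plus-strand reading frame is anchored so the AAA codon spans
chr7:70768042-70768044, and remaining bases are deterministic filler from a
fixed RNG.  All coordinate arithmetic downstream works on real hg38
coordinates; only the filler sequence is invented.
"""

from __future__ import annotations

import numpy as np

from .phasing import EditSite, GermlineSite, PhasingSites
from .reference import (
    AmpliconReference,
    CodingFrame,
    GuideDesign,
    COMPLEMENT,
    decode,
    validate_guide_against_reference,
)
from .simulate import CloneSpec, Haplotype

CONTIG = "chr7"

N044_PROTOSPACER = "CAAAAGTTGACCCATTCTAC"
N044_ANCHOR = 70768040  # plus strand; protospacer position 5 -> chr7:70768044
N068_PROTOSPACER = "TCACACTGTGCCGGTAGAAT"
N068_ANCHOR = 70768072  # minus strand; protospacer position 5 -> chr7:70768068

TARGET_H044 = 70768044
BYSTANDER_H044 = 70768043
TARGET_H068 = 70768068
GERMLINE_POSITION = 70768282  # rs3829006 G/A
GERMLINE_REF = "G"
GERMLINE_ALT = "A"

AMPLICON_START = 70767990
AMPLICON_LENGTH = 363  # the phasing PCR product length; covers both sites
_CODON_AAA_START = 70768042  # AAA (Lys) codon: chr7:70768042-70768044
_FILLER_SEED = 70768044  # fixed; the filler is part of the synthetic design


def _core_plus_strand() -> dict[int, str]:
    """Plus-strand bases chr7:70768040-70768072 implied by the two guides.

    The guides overlap over chr7:70768053-70768059; consistency there is
    asserted rather than assumed.
    """
    core: dict[int, str] = {}
    for k, base in enumerate(N044_PROTOSPACER, start=1):
        core[N044_ANCHOR + k - 1] = base
    for k, base in enumerate(N068_PROTOSPACER, start=1):
        pos = N068_ANCHOR - (k - 1)
        plus = base.translate(COMPLEMENT)
        if pos in core and core[pos] != plus:
            raise AssertionError(f"guide sequences disagree at {CONTIG}:{pos}")
        core[pos] = plus
    return core


def build_reference(name: str = "AUTS2_exon10_amplicon") -> AmpliconReference:
    """The synthetic surrogate amplicon (see module docstring)."""
    rng = np.random.default_rng(_FILLER_SEED)
    seq = list(decode(rng.integers(0, 4, AMPLICON_LENGTH).astype(np.uint8)))
    for pos, base in _core_plus_strand().items():
        seq[pos - AMPLICON_START] = base
    seq[GERMLINE_POSITION - AMPLICON_START] = GERMLINE_REF
    frame_offset = (_CODON_AAA_START - AMPLICON_START) % 3
    ref = AmpliconReference(
        name=name,
        contig=CONTIG,
        genomic_start=AMPLICON_START,
        sequence="".join(seq),
        coding_frame=CodingFrame(frame_offset=frame_offset, strand="+"),
    )
    validate_guide_against_reference(guide_n044(), ref)
    validate_guide_against_reference(guide_n068(), ref)
    return ref


def guide_n044(window: tuple[int, int] = (4, 7)) -> GuideDesign:
    return GuideDesign(
        guide_id="N044",
        protospacer=N044_PROTOSPACER,
        strand="+",
        anchor=N044_ANCHOR,
        target_position=5,
        window=window,
        contig=CONTIG,
    )


def guide_n068(window: tuple[int, int] = (4, 7)) -> GuideDesign:
    return GuideDesign(
        guide_id="N068",
        protospacer=N068_PROTOSPACER,
        strand="-",
        anchor=N068_ANCHOR,
        target_position=5,
        window=window,
        contig=CONTIG,
    )


def phasing_sites() -> PhasingSites:
    """The induced edit and rs3829006, 238 bp apart."""
    return PhasingSites(
        edit_site=EditSite(position=TARGET_H044, ref="A", alt="G"),
        germline_site=GermlineSite(
            position=GERMLINE_POSITION, allele1=GERMLINE_REF, allele2=GERMLINE_ALT
        ),
    )


# --- cohort design ---------------------------------------------------------
#
# The synthetic screening cohort mirrors the assay's screening round:
# 69 clones edited with H044 (guide N044) and 48 with H068 (guide N068).
# Haplotype weights are fixed by design so that, by construction,
#   * H044: 37/69 clones carry some window edit at >=2 % (31 at the target,
#     6 bystander-only), 9/69 carry the target edit at >=30 % (incl. two
#     potential homozygotes at 0.68 and 0.89), 12/69 are positive at the
#     position-4 bystander;
#   * H068: 15/48 carry the target edit at >=2 %, 2/48 at >=30 %.
# Weights keep >=4 sigma clearance from every classification threshold at
# 2,000x depth so sampling noise cannot move a clone across a band.

_H044_HIGH = (0.35, 0.38, 0.42, 0.45, 0.48, 0.52, 0.55, 0.68, 0.89)
_H044_LOW = tuple(round(w, 3) for w in np.linspace(0.05, 0.25, 22))
_H044_LOW_BYSTANDER = (0.05, 0.06, 0.08, 0.10, 0.12, 0.15)  # paired with first 6 low clones
_H044_BYSTANDER_ONLY = (0.05, 0.07, 0.09, 0.12, 0.16, 0.20)
_H044_UNEDITED = 32

_H068_HIGH = (0.42, 0.50)
_H068_LOW = tuple(round(w, 3) for w in np.linspace(0.05, 0.25, 13))
_H068_UNEDITED = 33


def _clone(sample_id: str, guide_id: str, ref: AmpliconReference,
           subs_weights: list[tuple[tuple[tuple[int, str], ...], float]]) -> CloneSpec:
    haps = []
    total = 0.0
    for i, (subs, w) in enumerate(subs_weights):
        label = "wt" if not subs else "+".join(f"{p}{b}" for p, b in subs)
        haps.append(Haplotype(label=label, substitutions=subs, weight=w))
        total += w
    if total < 1.0 - 1e-12:
        haps.append(Haplotype(label="wt", substitutions=(), weight=round(1.0 - total, 12)))
    return CloneSpec(sample_id=sample_id, haplotypes=tuple(haps), guide_id=guide_id)


def example_cohort(ref: AmpliconReference | None = None) -> list[CloneSpec]:
    """The 117-clone synthetic screening cohort (69 H044 + 48 H068)."""
    if ref is None:
        ref = build_reference()
    t44 = ref.to_offset(TARGET_H044) + 1  # 1-based amplicon positions
    b44 = ref.to_offset(BYSTANDER_H044) + 1
    t68 = ref.to_offset(TARGET_H068) + 1
    edit44 = ((t44, "G"),)
    by44 = ((b44, "G"),)
    edit68 = ((t68, "C"),)

    clones: list[CloneSpec] = []
    i = 0
    for w in _H044_HIGH:
        i += 1
        clones.append(_clone(f"H044_c{i:02d}", "N044", ref, [(edit44, w)]))
    for j, w in enumerate(_H044_LOW):
        i += 1
        extra = []
        if j < len(_H044_LOW_BYSTANDER):
            extra = [(by44, _H044_LOW_BYSTANDER[j])]
        clones.append(_clone(f"H044_c{i:02d}", "N044", ref, [(edit44, w)] + extra))
    for w in _H044_BYSTANDER_ONLY:
        i += 1
        clones.append(_clone(f"H044_c{i:02d}", "N044", ref, [(by44, w)]))
    for _ in range(_H044_UNEDITED):
        i += 1
        clones.append(_clone(f"H044_c{i:02d}", "N044", ref, []))

    i = 0
    for w in _H068_HIGH:
        i += 1
        clones.append(_clone(f"H068_c{i:02d}", "N068", ref, [(edit68, w)]))
    for w in _H068_LOW:
        i += 1
        clones.append(_clone(f"H068_c{i:02d}", "N068", ref, [(edit68, w)]))
    for _ in range(_H068_UNEDITED):
        i += 1
        clones.append(_clone(f"H068_c{i:02d}", "N068", ref, []))
    return clones
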