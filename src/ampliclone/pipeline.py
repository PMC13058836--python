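"""End-to-end conveniences: phase a sample, genotype a whole cohort.

These wrappers chain the module-level operations (simulate -> align ->
quantify -> classify / phase) the way the CLI, the examples and the
acceptance checks use them; nothing here adds behaviour beyond composition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .align import DEFAULT_MAX_EDIT_FRAC, DEFAULT_QUALITY_FLOOR
from .classify import ClassifierConfig, CloneCall, classify_clone
from .errors import NoPhaseError
from .phasing import PhasingResult, PhasingSites, count_joint_alleles, summarize_phasing
from .quantify import (
    AlleleFrequencyMatrix,
    ReadSource,
    SampleQuant,
    aggregate_matrix,
    iter_fragment_calls,
    quantify_sample,
)
from .reference import CODE_BASES, AmpliconReference, GuideDesign
from .simulate import CloneSpec, SimConfig, SimulatedClone, simulate_clone


def phase_sample(
    r1: ReadSource,
    r2: ReadSource,
    ref: AmpliconReference,
    sites: PhasingSites,
    quality_floor: int = DEFAULT_QUALITY_FLOOR,
    max_edit_frac: float = DEFAULT_MAX_EDIT_FRAC,
    min_fragments: int = 100,
    min_purity: float = 0.9,
    balance_tolerance: float = 0.15,
    edit_fraction_band: tuple[float, float] = (0.30, 0.65),
) -> PhasingResult:
    """Phase one sample's read pairs over the two sites.

    Fragments are aligned and mate-reconciled exactly as in quantification;
    each fragment's calls at the two site positions feed the joint table.
    Raises :class:`NoPhaseError` when no fragment is informative.
    """
    e_off = ref.to_offset(sites.edit_site.position)
    g_off = ref.to_offset(sites.germline_site.position)

    def _site_calls():
        for calls, _ in iter_fragment_calls(
            r1, r2, ref, quality_floor=quality_floor, max_edit_frac=max_edit_frac
        ):
            if not calls.mapped:
                yield {}
                continue
            out = {}
            for off, pos in ((e_off, sites.edit_site.position),
                             (g_off, sites.germline_site.position)):
                hit = np.flatnonzero(calls.positions == off)
                if hit.size == 1 and calls.codes[hit[0]] < 4:
                    out[pos] = CODE_BASES[calls.codes[hit[0]]]
            yield out

    table, uninformative = count_joint_alleles(_site_calls(), sites)
    if table.sum() == 0:
        raise NoPhaseError("zero informative fragments: cannot phase sample")
    return summarize_phasing(
        table,
        uninformative,
        min_fragments=min_fragments,
        min_purity=min_purity,
        balance_tolerance=balance_tolerance,
        edit_fraction_band=edit_fraction_band,
    )


@dataclass
class CohortRun:
    """Everything a simulated screening round produces."""

    quants: list[SampleQuant]
    calls: list[CloneCall]
    matrix: AlleleFrequencyMatrix
    clones: list[SimulatedClone]
    groups: dict[str, list[str]]


def run_simulated_cohort(
    ref: AmpliconReference,
    cohort: Sequence[CloneSpec],
    guides: Mapping[str, GuideDesign],
    sim_cfg: SimConfig,
    classifier_cfg: ClassifierConfig = ClassifierConfig(),
    seed: Optional[int] = None,
    keep_reads: bool = False,
) -> CohortRun:
    """Simulate, quantify and classify every clone of a cohort.

    Per-clone seeds are spawned deterministically from ``seed`` so the whole
    run is reproducible from one integer.
    """
    rng = np.random.default_rng(seed)
    quants: list[SampleQuant] = []
    calls: list[CloneCall] = []
    clones: list[SimulatedClone] = []
    groups: dict[str, list[str]] = {}
    for spec in cohort:
        clone_seed = int(rng.integers(0, 2**31 - 1))
        cfg = SimConfig(
            depth=sim_cfg.depth,
            read_length=sim_cfg.read_length,
            fragment_length=sim_cfg.fragment_length,
            fragment_start=sim_cfg.fragment_start,
            per_base_error=sim_cfg.per_base_error,
            base_quality=sim_cfg.base_quality,
            indel_rate=sim_cfg.indel_rate,
            seed=clone_seed,
        )
        clone = simulate_clone(ref, spec.haplotypes, cfg, clone_id=spec.sample_id)
        quant = quantify_sample(clone.r1, clone.r2, ref, sample_id=spec.sample_id)
        guide = guides[spec.guide_id]
        calls.append(classify_clone(quant, guide, classifier_cfg))
        quants.append(quant)
        groups.setdefault(spec.guide_id, []).append(spec.sample_id)
        if keep_reads:
            clones.append(clone)
    matrix = aggregate_matrix(quants)
    return CohortRun(quants=quants, calls=calls, matrix=matrix, clones=clones, groups=groups)
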