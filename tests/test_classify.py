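"""Clone triage: bands, efficiency rounding, mosaicism, bystanders."""

import numpy as np
import pytest

from ampliclone import (
    ClassifierConfig,
    DomainError,
    Haplotype,
    NoCallError,
    SimConfig,
    ValidationError,
    aggregate_matrix,
    classify_clone,
    positional_positivity_profile,
    quantify_sample,
    simulate_clone,
    summarize_efficiency,
)
from ampliclone.classify import (
    CATEGORY_HET,
    CATEGORY_HOM,
    CATEGORY_LOW,
    CATEGORY_UNEDITED,
)


def _classified(ref, guide, haps, depth=1000, error=0.0, seed=0,
                cfg=ClassifierConfig()):
    clone = simulate_clone(
        ref, haps, SimConfig(depth=depth, per_base_error=error, seed=seed), "c"
    )
    quant = quantify_sample(clone.r1, clone.r2, ref, sample_id="c")
    return clone, classify_clone(quant, guide, cfg)


def _edit(ref, coord, alt, weight, label="edit"):
    return Haplotype(label, ((ref.to_offset(coord) + 1, alt),), weight)


class TestCategoryBands:
    @pytest.mark.parametrize(
        "f,expected",
        [
            (0.0, CATEGORY_UNEDITED),
            (0.019, CATEGORY_UNEDITED),
            (0.02, CATEGORY_LOW),
            (0.29, CATEGORY_LOW),
            (0.30, CATEGORY_HET),
            (0.50, CATEGORY_HET),
            (0.649, CATEGORY_HET),
            (0.65, CATEGORY_HOM),
            (0.68, CATEGORY_HOM),
            (0.89, CATEGORY_HOM),
            (1.0, CATEGORY_HOM),
        ],
    )
    def test_band_assignment(self, f, expected):
        assert ClassifierConfig().category(f) == expected

    def test_band_partition_exhaustive(self):
        """Every fraction on a fine grid maps to exactly one category."""
        cfg = ClassifierConfig()
        cats = [cfg.category(f) for f in np.arange(0, 1.0001, 0.001)]
        assert set(cats) == {CATEGORY_UNEDITED, CATEGORY_LOW, CATEGORY_HET, CATEGORY_HOM}
        # non-decreasing band order along the sweep
        order = {CATEGORY_UNEDITED: 0, CATEGORY_LOW: 1, CATEGORY_HET: 2, CATEGORY_HOM: 3}
        ranks = [order[c] for c in cats]
        assert ranks == sorted(ranks)

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValidationError):
            ClassifierConfig(detect_threshold=0.5, het_threshold=0.3)


class TestClassifyClone:
    def test_potential_homozygote(self, ref, guide_n044):
        _, call = _classified(ref, guide_n044, [
            Haplotype("wt", (), 0.11), _edit(ref, 70768044, "G", 0.89)
        ])
        assert call.category == CATEGORY_HOM
        assert call.target_edit_fraction == pytest.approx(0.89, abs=0.05)

    def test_clean_wt_clone(self, ref, guide_n044):
        _, call = _classified(ref, guide_n044, [Haplotype("wt", (), 1.0)])
        assert call.category == CATEGORY_UNEDITED
        assert not call.mosaic
        assert call.bystander_edits == ()

    def test_het_with_subthreshold_bystander(self, ref, guide_n044):
        """50 % target edit plus a 3 % bystander at window position 4:
        heterozygous candidate, bystander listed, not mosaic (3 % < 5 %)."""
        _, call = _classified(
            ref,
            guide_n044,
            [
                Haplotype("wt", (), 0.47),
                _edit(ref, 70768044, "G", 0.50),
                _edit(ref, 70768043, "G", 0.03, label="bystander"),
            ],
            depth=4000,
            seed=2,
        )
        assert call.category == CATEGORY_HET
        assert [k for k, _ in call.bystander_edits] == [4]
        assert call.bystander_edits[0][1] == pytest.approx(0.03, abs=0.012)
        assert not call.mosaic

    def test_mosaic_flag_above_threshold(self, ref, guide_n044):
        _, call = _classified(
            ref,
            guide_n044,
            [
                Haplotype("wt", (), 0.42),
                _edit(ref, 70768044, "G", 0.50),
                _edit(ref, 70768043, "G", 0.08, label="bystander"),
            ],
            depth=4000,
            seed=3,
        )
        assert call.mosaic
        assert any(p == 70768043 for p, _, _ in call.mosaic_alleles)

    def test_unintended_offtarget_allele_is_mosaic(self, ref, guide_n044):
        off_pos = ref.genomic_start + 20
        alt = "A" if ref.base_at(off_pos) != "A" else "C"
        _, call = _classified(
            ref,
            guide_n044,
            [Haplotype("wt", (), 0.9), _edit(ref, off_pos, alt, 0.1, label="sub")],
            depth=4000,
            seed=4,
        )
        assert call.mosaic
        assert call.category == CATEGORY_UNEDITED

    def test_intended_edit_never_counts_as_mosaic(self, ref, guide_n044):
        _, call = _classified(ref, guide_n044, [
            Haplotype("wt", (), 0.5), _edit(ref, 70768044, "G", 0.5)
        ])
        assert not call.mosaic
        assert all(
            not (p == 70768044 and a == "G") for p, a, _ in call.mosaic_alleles
        )

    def test_zero_depth_target_no_call(self, ref, guide_n044):
        clone = simulate_clone(
            ref, [Haplotype("wt", (), 1.0)],
            SimConfig(depth=100, read_length=30, fragment_length=363,
                      per_base_error=0.0, seed=0),
            "c",
        )
        quant = quantify_sample(clone.r1, clone.r2, ref)
        with pytest.raises(NoCallError):
            classify_clone(quant, guide_n044, ClassifierConfig())

    def test_classifier_recovery_noiseless_bands(self, ref, guide_n044):
        """Across all bands, noiseless classification matches the band of
        the realised (not nominal) fraction: agreement is exact."""
        cfg = ClassifierConfig()
        for seed, w in enumerate((0.0, 0.01, 0.05, 0.3, 0.5, 0.68, 0.89, 1.0)):
            haps = [Haplotype("wt", (), 1.0)] if w == 0 else (
                [_edit(ref, 70768044, "G", 1.0)] if w == 1.0 else
                [Haplotype("wt", (), 1 - w), _edit(ref, 70768044, "G", w)]
            )
            clone, call = _classified(ref, guide_n044, haps, depth=2000, seed=seed)
            realised = clone.truth_fraction("edit") if w > 0 else 0.0
            assert call.category == cfg.category(realised)


class TestSummarizeEfficiency:
    @pytest.mark.parametrize(
        "positives,total,expected",
        [(37, 69, 54), (9, 69, 13), (15, 48, 31), (2, 48, 4), (0, 48, 0), (69, 69, 100)],
    )
    def test_printed_ratios_round_half_up(self, positives, total, expected):
        assert summarize_efficiency((positives, total)) == expected

    def test_half_up_rounding_edge(self):
        assert summarize_efficiency((1, 200)) == 1  # 0.5 -> 1, half-up
        assert summarize_efficiency((1, 201)) == 0

    def test_zero_total_rejected(self):
        with pytest.raises(DomainError):
            summarize_efficiency((0, 0))

    def test_monotone_in_threshold(self, ref, guide_n044):
        calls = []
        for seed, w in enumerate((0.0, 0.05, 0.15, 0.35, 0.6, 0.9)):
            haps = [Haplotype("wt", (), 1.0)] if w == 0 else [
                Haplotype("wt", (), 1 - w), _edit(ref, 70768044, "G", w)
            ]
            calls.append(_classified(ref, guide_n044, haps, depth=500, seed=seed)[1])
        effs = [summarize_efficiency(calls, t) for t in (0.01, 0.02, 0.1, 0.3, 0.5, 0.95)]
        assert effs == sorted(effs, reverse=True)


class TestPositivityProfile:
    def test_all_zero_matrix(self, ref):
        clones = [
            simulate_clone(ref, [Haplotype("wt", (), 1.0)],
                           SimConfig(depth=100, per_base_error=0.0, seed=s), f"s{s}")
            for s in range(3)
        ]
        quants = [quantify_sample(c.r1, c.r2, ref, sample_id=c.clone_id) for c in clones]
        m = aggregate_matrix(quants)
        profile = positional_positivity_profile(m, 0.02)
        assert (profile == 0).all()

    def test_profile_peak_matches_design(self, ref):
        """6/10 clones positive at the target -> profile value 0.6 there."""
        quants = []
        for s in range(10):
            w = 0.4 if s < 6 else 0.0
            haps = [Haplotype("wt", (), 1.0)] if w == 0 else [
                Haplotype("wt", (), 1 - w), _edit(ref, 70768044, "G", w)
            ]
            c = simulate_clone(ref, haps, SimConfig(depth=400, seed=s), f"s{s}")
            quants.append(quantify_sample(c.r1, c.r2, ref, sample_id=f"s{s}"))
        profile = positional_positivity_profile(aggregate_matrix(quants), 0.02)
        assert profile[70768044] == pytest.approx(0.6)

    def test_threshold_above_one_gives_zero(self, ref):
        c = simulate_clone(ref, [Haplotype("wt", (), 1.0)],
                           SimConfig(depth=50, seed=0), "s0")
        m = aggregate_matrix([quantify_sample(c.r1, c.r2, ref, sample_id="s0")])
        assert (positional_positivity_profile(m, 1.01) == 0).all()
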