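"""Cohort-level reporting: matrices, positivity profiles, roster, shortlist.

The report layer turns per-clone quantifications and calls into the flat
files a screening campaign is actually steered by: the samples x positions
allele-frequency matrix, per-guide-group positivity profiles (the line
graphs used to read off the editing window), the full clone roster and the
shortlist of clones worth expanding (non-mosaic heterozygous candidates).
Plots are a thin optional layer rendered from the exported TSVs — never
from in-memory state — so every figure is reproducible from the files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .classify import (
    CATEGORY_HET,
    CATEGORIES,
    ClassifierConfig,
    CloneCall,
    positional_positivity_profile,
    summarize_efficiency,
)
from .errors import ValidationError
from .quantify import AlleleFrequencyMatrix

MATRIX_FLOAT_FORMAT = "%.6f"


@dataclass
class CohortReport:
    """In-memory counterpart of the exported cohort files."""

    profiles: dict[str, pd.Series]
    efficiency: dict[str, dict[str, int]]
    roster: pd.DataFrame
    shortlist: pd.DataFrame


def calls_to_frame(calls: Sequence[CloneCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "sample_id": c.sample_id,
                "target_position": c.target_position,
                "target_edit_fraction": c.target_edit_fraction,
                "target_depth": c.target_depth,
                "category": c.category,
                "mosaic": c.mosaic,
                "mosaic_alleles": ";".join(
                    f"{p}:{a}:{f:.4f}" for p, a, f in c.mosaic_alleles
                ),
                "bystander_edits": ";".join(f"{k}:{f:.4f}" for k, f in c.bystander_edits),
            }
        )
    return pd.DataFrame(rows)


def write_matrix(matrix: AlleleFrequencyMatrix, path: Path | str) -> None:
    """Write the values matrix (and a sibling ``.depth.tsv``) as TSV.

    Values are formatted at 6 decimal places; re-reading reproduces them
    bit-exactly at that precision.
    """
    path = Path(path)
    matrix.values.to_csv(path, sep="\t", float_format=MATRIX_FLOAT_FORMAT, index_label="sample_id")
    matrix.depth.to_csv(path.with_suffix(".depth.tsv"), sep="\t", index_label="sample_id")


def read_matrix(path: Path | str) -> AlleleFrequencyMatrix:
    path = Path(path)
    values = pd.read_csv(path, sep="\t", index_col="sample_id")
    values.columns = values.columns.astype(int)
    values.index.name = None
    depth_path = path.with_suffix(".depth.tsv")
    if depth_path.exists():
        depth = pd.read_csv(depth_path, sep="\t", index_col="sample_id")
        depth.columns = depth.columns.astype(int)
        depth.index.name = None
    else:
        depth = pd.DataFrame(0, index=values.index, columns=values.columns)
    return AlleleFrequencyMatrix(values=values, depth=depth)


def export_cohort(
    matrix: AlleleFrequencyMatrix,
    calls: Sequence[CloneCall],
    groups: Mapping[str, Sequence[str]],
    outdir: Path | str,
    cfg: ClassifierConfig = ClassifierConfig(),
) -> CohortReport:
    """Write the cohort report files and return their in-memory form.

    ``groups`` maps a group name (typically the guide) to its sample ids;
    every referenced sample must exist in both the matrix and the calls.
    """
    if not calls or not len(matrix.values):
        raise ValidationError("cannot export an empty cohort")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    roster = calls_to_frame(calls)
    known = set(roster["sample_id"]) & set(matrix.values.index)
    for group, ids in groups.items():
        unknown = [s for s in ids if s not in known]
        if unknown:
            raise ValidationError(f"group {group!r} references unknown samples {unknown}")

    write_matrix(matrix, outdir / "matrix.tsv")
    roster.to_csv(outdir / "roster.tsv", sep="\t", index=False, float_format="%.6f")

    shortlist = roster[(~roster["mosaic"]) & (roster["category"] == CATEGORY_HET)]
    shortlist.to_csv(outdir / "shortlist.tsv", sep="\t", index=False, float_format="%.6f")

    profiles: dict[str, pd.Series] = {}
    efficiency: dict[str, dict[str, int]] = {}
    by_id = {c.sample_id: c for c in calls}
    for group, ids in groups.items():
        sub = AlleleFrequencyMatrix(
            values=matrix.values.loc[list(ids)], depth=matrix.depth.loc[list(ids)]
        )
        profile = positional_positivity_profile(sub, threshold=cfg.detect_threshold)
        profile.rename("positive_fraction").to_csv(
            outdir / f"profile_{group}.tsv", sep="\t", index_label="position",
            float_format="%.6f",
        )
        profiles[group] = profile
        group_calls = [by_id[s] for s in ids]
        efficiency[group] = {
            "n_clones": len(group_calls),
            "efficiency_detect_pct": summarize_efficiency(group_calls, cfg.detect_threshold),
            "efficiency_het_pct": summarize_efficiency(group_calls, cfg.het_threshold),
            **{
                f"n_{cat}": sum(1 for c in group_calls if c.category == cat)
                for cat in CATEGORIES
            },
            "n_mosaic": sum(1 for c in group_calls if c.mosaic),
        }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(efficiency, fh, indent=2)
    return CohortReport(
        profiles=profiles, efficiency=efficiency, roster=roster, shortlist=shortlist
    )


def plot_profiles(
    profile_paths: Sequence[Path | str],
    out_png: Path | str,
    title: str = "Positional clone positivity",
) -> None:
    """Line graph of one or more exported positivity-profile TSVs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3.5))
    for path in profile_paths:
        path = Path(path)
        df = pd.read_csv(path, sep="\t")
        ax.plot(df["position"], 100 * df["positive_fraction"], label=path.stem)
    ax.set_xlabel("genomic position")
    ax.set_ylabel("% positive clones")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_png, dpi=150)
    plt.close(fig)
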