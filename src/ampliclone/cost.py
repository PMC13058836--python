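"""Sanger-vs-NGS genotyping cost model with crossover computation.

Sanger cost is linear in the number of samples N.  Amplicon-NGS cost has a
fixed run component, a (small) per-sample sequencing component, and — when
index primers must be synthesised — a dual-index primer component: with two
index axes, ceil(sqrt(N)) primers per axis suffice to index N samples, so
primer cost grows as ~sqrt(N) rather than N.  The crossover is the smallest
N at which NGS becomes strictly cheaper; it is found by exact integer scan,
which also handles the non-monotone steps the ceiling introduces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .errors import ValidationError


@dataclass(frozen=True)
class CostParams:
    """Per-unit costs in any fixed currency."""

    sanger_per_sample: float
    ngs_seq_per_sample: float
    ngs_fixed: float = 0.0
    index_primer_unit_cost: float = 0.0

    def __post_init__(self) -> None:
        if min(
            self.sanger_per_sample,
            self.ngs_seq_per_sample,
            self.ngs_fixed,
            self.index_primer_unit_cost,
        ) < 0:
            raise ValidationError("all costs must be >= 0")


def primers_needed(n: int) -> int:
    """Index primers to synthesise for n samples: two axes of ceil(sqrt(n))."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    root = math.isqrt(n)
    if root * root < n:
        root += 1
    return 2 * root


def sanger_cost(params: CostParams, n: int) -> float:
    return params.sanger_per_sample * n


def ngs_cost(params: CostParams, n: int, include_primers: bool = True) -> float:
    cost = params.ngs_fixed + params.ngs_seq_per_sample * n
    if include_primers:
        cost += params.index_primer_unit_cost * primers_needed(n)
    return cost


def cost_curves(params: CostParams, n_max: int) -> pd.DataFrame:
    """Per-N costs for 1 <= N <= n_max, one row per N."""
    if n_max < 1:
        raise ValidationError("n_max must be >= 1")
    rows = {
        "n_samples": range(1, n_max + 1),
        "sanger": [sanger_cost(params, n) for n in range(1, n_max + 1)],
        "ngs_without_primers": [ngs_cost(params, n, False) for n in range(1, n_max + 1)],
        "ngs_with_primers": [ngs_cost(params, n, True) for n in range(1, n_max + 1)],
    }
    return pd.DataFrame(rows)


def crossover(
    params: CostParams, include_primers: bool = True, n_max: int = 10_000
) -> Optional[int]:
    """Smallest N with NGS strictly cheaper than Sanger; None if never
    within 1..n_max."""
    for n in range(1, n_max + 1):
        if ngs_cost(params, n, include_primers) < sanger_cost(params, n):
            return n
    return None


def example_cost_params() -> CostParams:
    """Illustrative dual-index amplicon costing.

    A calibration (Sanger 10/sample; NGS 1/sample sequencing, 65 fixed,
    36.5 per index primer) under which NGS overtakes Sanger at 81 samples
    when primer synthesis is included and at 8 samples when an existing
    primer set is reused.
    """
    return CostParams(
        sanger_per_sample=10.0,
        ngs_seq_per_sample=1.0,
        ngs_fixed=65.0,
        index_primer_unit_cost=36.5,
    )
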