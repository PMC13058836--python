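"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from ampliclone import auts2


@pytest.fixture(scope="session")
def ref():
    return auts2.build_reference()


@pytest.fixture(scope="session")
def guide_n044():
    return auts2.guide_n044()


@pytest.fixture(scope="session")
def guide_n068():
    return auts2.guide_n068()


@pytest.fixture(scope="session")
def sites():
    return auts2.phasing_sites()


# --- independent oracles ---------------------------------------------------

def semiglobal_edit_distance(query: str, target: str) -> int:
    """Full dynamic-programming semi-global edit distance (free end-gaps on
    the target), unit costs.  Deliberately naive: the oracle against which
    the package's aligner is checked."""
    n = len(target)
    prev = [0] * (n + 1)
    for i, qc in enumerate(query, 1):
        cur = [i] + [0] * n
        for j, tc in enumerate(target, 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (qc != tc))
        prev = cur
    return min(prev)


#: hard-coded standard nuclear genetic code (independent of Biopython)
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def mutate_read(rng: np.random.Generator, read: str, n_edits: int) -> str:
    """Apply ``n_edits`` random substitutions/insertions/deletions."""
    bases = "ACGT"
    s = list(read)
    for _ in range(n_edits):
        kind = rng.integers(0, 3)
        pos = int(rng.integers(0, len(s))) if s else 0
        if kind == 0 and s:  # substitution
            old = s[pos]
            s[pos] = bases[(bases.index(old) + int(rng.integers(1, 4))) % 4]
        elif kind == 1:  # insertion
            s.insert(pos, bases[int(rng.integers(0, 4))])
        elif s:  # deletion
            s.pop(pos)
    return "".join(s)
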