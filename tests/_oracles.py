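"""Independent brute-force oracles used only by the tests.

These are deliberately separate code paths from the package: a plain
Gotoh local-alignment scorer over full numpy matrices, and a literal
standard-genetic-code enumeration from the classic 64-codon string.
"""

from __future__ import annotations

from itertools import product
from typing import Dict, FrozenSet

import numpy as np

# Standard genetic code, TCAG ordering, '*' = stop.
_CODE64 = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
_BASES = "TCAG"


def standard_codon_table() -> Dict[str, str]:
    """codon → amino acid for the 61 sense codons, by direct enumeration."""
    table = {}
    for (b1, b2, b3), aa in zip(product(_BASES, repeat=3), _CODE64):
        if aa != "*":
            table[b1 + b2 + b3] = aa
    return table


def second_position_sets() -> Dict[str, FrozenSet[str]]:
    """Brute-force 1-L mapping: distinct letters at codon position 2."""
    out: Dict[str, set] = {}
    for codon, aa in standard_codon_table().items():
        out.setdefault(aa, set()).add(codon[1])
    return {aa: frozenset(v) for aa, v in out.items()}


def sw_score(
    query: str,
    subject: str,
    match: int = 2,
    mismatch: int = -3,
    gap_open: int = 5,
    gap_extend: int = 2,
) -> int:
    """Best local-alignment score, affine gaps (cost open + len·extend).

    N is treated as matching nothing.  Full O(mn) matrices, no seeding,
    no shortcuts — the ground truth for the seeded aligner.
    """
    m, n = len(query), len(subject)
    neg = np.iinfo(np.int64).min // 4
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    E = np.full((m + 1, n + 1), neg, dtype=np.int64)
    F = np.full((m + 1, n + 1), neg, dtype=np.int64)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = match if (query[i - 1] == subject[j - 1] and query[i - 1] != "N") else mismatch
            E[i, j] = max(H[i, j - 1] - gap_open - gap_extend, E[i, j - 1] - gap_extend)
            F[i, j] = max(H[i - 1, j] - gap_open - gap_extend, F[i - 1, j] - gap_extend)
            H[i, j] = max(0, H[i - 1, j - 1] + s, E[i, j], F[i, j])
    return int(H.max())


def revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[c] for c in reversed(seq))


def shares_word(query: str, subject: str, w: int) -> bool:
    words = {query[i : i + w] for i in range(len(query) - w + 1)}
    return any(subject[j : j + w] in words for j in range(len(subject) - w + 1))
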