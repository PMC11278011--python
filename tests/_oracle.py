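"""Independent brute-force oracles used only by the tests.

The local aligner oracle is a plain Gotoh dynamic programme written
directly from the recurrences, kept independent of the package's
alignment engine.  Gap convention: a gap of length L costs
open + (L - 1) * extend, i.e. the opening penalty is charged to the
first gap column.
"""

from __future__ import annotations

import numpy as np
from biotite.sequence.align import SubstitutionMatrix

_MAT = SubstitutionMatrix.std_protein_matrix()
_ALPHA = {c: i for i, c in enumerate(str(a) for a in _MAT.get_alphabet1())}
_SCORES = np.asarray(_MAT.score_matrix())

NEG = -(10 ** 9)


def smith_waterman_score(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Best local alignment score under BLOSUM62 with affine gaps."""
    ai = np.array([_ALPHA[c] for c in a])
    bi = np.array([_ALPHA[c] for c in b])
    n, m = len(ai), len(bi)
    sub = _SCORES[np.ix_(ai, bi)]
    H = np.zeros(m + 1, dtype=np.int64)      # best ending in match state
    E = np.full(m + 1, NEG, dtype=np.int64)  # gap in a (horizontal)
    F = np.full(m + 1, NEG, dtype=np.int64)  # gap in b (vertical)
    best = 0
    prev_H = H.copy()
    for i in range(1, n + 1):
        H = np.zeros(m + 1, dtype=np.int64)
        F = np.maximum(prev_H - gap_open, F - gap_extend)
        E_row = NEG
        for j in range(1, m + 1):
            E_row = max(H[j - 1] - gap_open, E_row - gap_extend)
            h = max(0, prev_H[j - 1] + sub[i - 1, j - 1], E_row, F[j])
            H[j] = h
            if h > best:
                best = h
        prev_H = H
    return int(best)


def hamming(a: str, b: str) -> int:
    assert len(a) == len(b)
    return sum(1 for x, y in zip(a, b) if x != y)
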