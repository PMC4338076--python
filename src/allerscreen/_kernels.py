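"""Numba dynamic-programming kernels for local alignment.

Gap convention: a gap of length g costs gap_open + gap_extend*(g-1),
i.e. the first gapped residue pays the full opening cost (the classic
FASTA "-12/-2" parameterisation).
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(10**9)


@njit(cache=True)
def gotoh_matrices(q, s, sub, gap_open, gap_extend):
    """Fill the H/E/F affine-gap matrices (Gotoh 1982 recurrences).

    H holds the best local score ending at (i, j); E ends in a gap in
    the query row (consuming subject), F in a gap in the subject row
    (consuming query).
    """
    m = q.shape[0]
    n = s.shape[0]
    H = np.zeros((m + 1, n + 1), np.int64)
    E = np.full((m + 1, n + 1), NEG, np.int64)
    F = np.full((m + 1, n + 1), NEG, np.int64)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e = H[i, j - 1] - gap_open
            e2 = E[i, j - 1] - gap_extend
            if e2 > e:
                e = e2
            f = H[i - 1, j] - gap_open
            f2 = F[i - 1, j] - gap_extend
            if f2 > f:
                f = f2
            E[i, j] = e
            F[i, j] = f
            h = H[i - 1, j - 1] + sub[q[i - 1], s[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
    return H, E, F


@njit(cache=True)
def sw_score(q, s, sub, gap_open, gap_extend):
    """Optimal local alignment score only, O(n) memory."""
    m = q.shape[0]
    n = s.shape[0]
    Hp = np.zeros(n + 1, np.int64)
    Fp = np.full(n + 1, NEG, np.int64)
    best = 0
    for i in range(m):
        Hc = np.zeros(n + 1, np.int64)
        Fc = np.full(n + 1, NEG, np.int64)
        e = NEG
        for j in range(1, n + 1):
            e0 = Hc[j - 1] - gap_open
            e1 = e - gap_extend
            e = e0 if e0 > e1 else e1
            f0 = Hp[j] - gap_open
            f1 = Fp[j] - gap_extend
            f = f0 if f0 > f1 else f1
            Fc[j] = f
            h = Hp[j - 1] + sub[q[i], s[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            Hc[j] = h
            if h > best:
                best = h
        Hp = Hc
        Fp = Fc
    return best
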