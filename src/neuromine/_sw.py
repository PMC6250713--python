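"""Numba kernels for affine-gap Smith-Waterman alignment.

Gap convention: a gap of length L costs gap_open + (L-1)*gap_extend, i.e. the
first gapped position pays the (negative) open penalty and each further
position the extend penalty.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = np.int32(-(10 ** 8))


@njit(cache=False)
def sw_score(a, b, matrix, gap_open, gap_extend):
    """Optimal local alignment score of int-encoded sequences a and b.

    Linear-memory Gotoh recurrence: E is the horizontal-gap state (scalar
    running along the row), F the vertical-gap state (one slot per column).
    """
    n, m = a.shape[0], b.shape[0]
    Hprev = np.zeros(m + 1, dtype=np.int32)
    Hcur = np.zeros(m + 1, dtype=np.int32)
    F = np.full(m + 1, NEG, dtype=np.int32)
    best = np.int32(0)
    for i in range(1, n + 1):
        Ecur = NEG
        prevH = np.int32(0)
        Hcur[0] = 0
        for j in range(1, m + 1):
            e_open = prevH + gap_open
            e_ext = Ecur + gap_extend
            Ecur = e_open if e_open >= e_ext else e_ext
            f_open = Hprev[j] + gap_open
            f_ext = F[j] + gap_extend
            F[j] = f_open if f_open >= f_ext else f_ext
            h = Hprev[j - 1] + matrix[a[i - 1], b[j - 1]]
            if F[j] > h:
                h = F[j]
            if Ecur > h:
                h = Ecur
            if h < 0:
                h = 0
            Hcur[j] = h
            prevH = h
            if h > best:
                best = h
        Hprev, Hcur = Hcur, Hprev
    return best


@njit(cache=False)
def sw_full(a, b, matrix, gap_open, gap_extend):
    """Full Smith-Waterman DP with traceback pointers.

    Returns (score, end_i, end_j, ptrH, ptrE, ptrF) where ptrH codes the move
    that achieved H[i][j]: 0 stop, 1 diagonal, 2 vertical (gap in b),
    3 horizontal (gap in a); ptrE/ptrF code 1 when the gap was extended.
    The best cell is the first maximum in row-major order (earliest end).
    Ties within a cell prefer diagonal > vertical > horizontal.
    """
    n, m = a.shape[0], b.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    ptrH = np.zeros((n + 1, m + 1), dtype=np.uint8)
    ptrE = np.zeros((n + 1, m + 1), dtype=np.uint8)
    ptrF = np.zeros((n + 1, m + 1), dtype=np.uint8)
    best = np.int32(0)
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e_open = H[i, j - 1] + gap_open
            e_ext = E[i, j - 1] + gap_extend
            if e_ext > e_open:
                E[i, j] = e_ext
                ptrE[i, j] = 1
            else:
                E[i, j] = e_open
            f_open = H[i - 1, j] + gap_open
            f_ext = F[i - 1, j] + gap_extend
            if f_ext > f_open:
                F[i, j] = f_ext
                ptrF[i, j] = 1
            else:
                F[i, j] = f_open
            s = H[i - 1, j - 1] + matrix[a[i - 1], b[j - 1]]
            h = np.int32(0)
            p = np.uint8(0)
            if s > h:
                h = s
                p = 1
            if F[i, j] > h:
                h = F[i, j]
                p = 2
            if E[i, j] > h:
                h = E[i, j]
                p = 3
            H[i, j] = h
            ptrH[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj, ptrH, ptrE, ptrF
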