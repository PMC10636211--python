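"""Low-level affine-gap local-alignment kernels (numba).

These kernels are shared by the full Smith-Waterman oracle and the seeded
search's windowed gapped extension.  Gap cost convention follows BLAST: a
gap of length L costs ``gap_open + L * gap_extend``.

Traceback pointers: 0 = stop, 1 = diagonal, 2 = up (gap in subject),
3 = left (gap in query).  Tie-break on equal scores: diagonal > up > left,
which makes tracebacks deterministic.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def sw_matrices(q, s, sub, gap_open, gap_extend):  # pragma: no cover - numba
    m = q.shape[0]
    n = s.shape[0]
    H = np.zeros((m + 1, n + 1), np.int32)
    E = np.full((m + 1, n + 1), -10**8, np.int32)  # gap in query (left)
    F = np.full((m + 1, n + 1), -10**8, np.int32)  # gap in subject (up)
    ptr = np.zeros((m + 1, n + 1), np.uint8)
    ptrE = np.zeros((m + 1, n + 1), np.uint8)  # 1 -> E came from E (extend)
    ptrF = np.zeros((m + 1, n + 1), np.uint8)
    best = 0
    bi = 0
    bj = 0
    go = gap_open + gap_extend
    ge = gap_extend
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            e_open = H[i, j - 1] - go
            e_ext = E[i, j - 1] - ge
            if e_ext > e_open:
                E[i, j] = e_ext
                ptrE[i, j] = 1
            else:
                E[i, j] = e_open
                ptrE[i, j] = 0
            f_open = H[i - 1, j] - go
            f_ext = F[i - 1, j] - ge
            if f_ext > f_open:
                F[i, j] = f_ext
                ptrF[i, j] = 1
            else:
                F[i, j] = f_open
                ptrF[i, j] = 0
            d = H[i - 1, j - 1] + sub[qi, s[j - 1]]
            # priority on ties: diagonal > up (F) > left (E) > stop
            h = 0
            p = 0
            if d >= h and d >= F[i, j] and d >= E[i, j]:
                h = d
                p = 1
            elif F[i, j] >= h and F[i, j] >= E[i, j]:
                h = F[i, j]
                p = 2
            elif E[i, j] >= h:
                h = E[i, j]
                p = 3
            if h <= 0:
                h = 0
                p = 0
            H[i, j] = h
            ptr[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj, ptr, ptrE, ptrF


@njit(cache=False)
def sw_score_only(q, s, sub, gap_open, gap_extend):  # pragma: no cover - numba
    """Linear-memory Smith-Waterman score (no traceback)."""
    m = q.shape[0]
    n = s.shape[0]
    H_prev = np.zeros(n + 1, np.int32)
    H_cur = np.zeros(n + 1, np.int32)
    E = np.full(n + 1, -10**8, np.int32)
    F = np.full(n + 1, -10**8, np.int32)
    best = 0
    go = gap_open + gap_extend
    ge = gap_extend
    for i in range(1, m + 1):
        qi = q[i - 1]
        H_cur[0] = 0
        F_prev_row = F  # F indexed by column
        for j in range(1, n + 1):
            e = H_cur[j - 1] - go
            e2 = E[j - 1] - ge
            if e2 > e:
                e = e2
            E[j] = e
            f = H_prev[j] - go
            f2 = F_prev_row[j] - ge
            if f2 > f:
                f = f2
            F[j] = f
            h = H_prev[j - 1] + sub[qi, s[j - 1]]
            if f > h:
                h = f
            if e > h:
                h = e
            if h < 0:
                h = 0
            H_cur[j] = h
            if h > best:
                best = h
        tmp = H_prev
        H_prev = H_cur
        H_cur = tmp
    return best


@njit(cache=False)
def ungapped_extend(q, s, sub, qpos, spos, k, x_drop):  # pragma: no cover - numba
    """X-drop ungapped extension of an exact k-mer seed.

    Returns (score, q_start, q_end, s_start, s_end) of the best-scoring
    ungapped segment through the seed (half-open aa coordinates).
    """
    score = 0
    for t in range(k):
        score += sub[q[qpos + t], s[spos + t]]
    best = score
    best_right_q = qpos + k
    # extend right
    cur = score
    i = qpos + k
    j = spos + k
    while i < q.shape[0] and j < s.shape[0]:
        cur += sub[q[i], s[j]]
        if cur > best:
            best = cur
            best_right_q = i + 1
        if best - cur > x_drop:
            break
        i += 1
        j += 1
    # extend left
    cur = best
    total_best = best
    best_left_q = qpos
    i = qpos - 1
    j = spos - 1
    while i >= 0 and j >= 0:
        cur += sub[q[i], s[j]]
        if cur > total_best:
            total_best = cur
            best_left_q = i
        if total_best - cur > x_drop:
            break
        i -= 1
        j -= 1
    diag = spos - qpos
    return total_best, best_left_q, best_right_q, best_left_q + diag, best_right_q + diag
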