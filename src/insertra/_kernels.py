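"""Numba DP kernels for affine-gap local alignment.

Convention: query ``a`` on rows, reference ``b`` on columns. A gap of length g
costs ``gap_open + g * gap_extend`` (both passed as negative numbers). Pointer
codes in ``ptr_h``: 0 = local stop (H hit zero), 1 = diagonal, 2 = horizontal
(consumes reference only), 3 = vertical (consumes query only).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def sw_affine(a, b, match, mismatch, gap_open, gap_extend):
    n = a.size
    m = b.size
    h_prev = np.zeros(m + 1, dtype=np.int32)
    h_cur = np.zeros(m + 1, dtype=np.int32)
    f = np.full(m + 1, -(10**8), dtype=np.int32)  # vertical state per column
    ptr_h = np.zeros((n + 1, m + 1), dtype=np.uint8)
    ptr_e = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 1 = extended gap
    ptr_f = np.zeros((n + 1, m + 1), dtype=np.uint8)
    best = np.int32(0)
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        e = np.int32(-(10**8))  # horizontal state within the row
        h_cur[0] = 0
        ai = a[i - 1]
        for j in range(1, m + 1):
            # horizontal: gap consuming reference
            e_open = h_cur[j - 1] + gap_open + gap_extend
            e_ext = e + gap_extend
            if e_ext > e_open:
                e = e_ext
                ptr_e[i, j] = 1
            else:
                e = e_open
                ptr_e[i, j] = 0
            # vertical: gap consuming query
            f_open = h_prev[j] + gap_open + gap_extend
            f_ext = f[j] + gap_extend
            if f_ext > f_open:
                f[j] = f_ext
                ptr_f[i, j] = 1
            else:
                f[j] = f_open
                ptr_f[i, j] = 0
            s = match if ai == b[j - 1] else mismatch
            diag = h_prev[j - 1] + s
            h = diag
            p = np.uint8(1)
            if e > h:
                h = e
                p = np.uint8(2)
            if f[j] > h:
                h = f[j]
                p = np.uint8(3)
            if h <= 0:
                h = 0
                p = np.uint8(0)
            h_cur[j] = h
            ptr_h[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
        tmp = h_prev
        h_prev = h_cur
        h_cur = tmp
    return best, bi, bj, ptr_h, ptr_e, ptr_f


@njit(cache=True)
def banded_score(a, b, match, mismatch, gap_open, gap_extend):
    """Score-only variant (no pointers); used where only the score matters."""
    n = a.size
    m = b.size
    h_prev = np.zeros(m + 1, dtype=np.int32)
    h_cur = np.zeros(m + 1, dtype=np.int32)
    f = np.full(m + 1, -(10**8), dtype=np.int32)
    best = np.int32(0)
    for i in range(1, n + 1):
        e = np.int32(-(10**8))
        h_cur[0] = 0
        ai = a[i - 1]
        for j in range(1, m + 1):
            e = max(e + gap_extend, h_cur[j - 1] + gap_open + gap_extend)
            f[j] = max(f[j] + gap_extend, h_prev[j] + gap_open + gap_extend)
            s = match if ai == b[j - 1] else mismatch
            h = h_prev[j - 1] + s
            if e > h:
                h = e
            if f[j] > h:
                h = f[j]
            if h < 0:
                h = 0
            h_cur[j] = h
            if h > best:
                best = h
        tmp = h_prev
        h_prev = h_cur
        h_cur = tmp
    return best


@njit(cache=True)
def hamming_best_window(read, ref, start_lo, start_hi):
    """Best ungapped placement of ``read`` over ref starts in [start_lo, start_hi];
    returns (best_start, n_mismatches). Fast path for substitution-only data."""
    best_start = start_lo
    best_mm = read.size + 1
    for s in range(start_lo, start_hi + 1):
        if s < 0 or s + read.size > ref.size:
            continue
        mm = 0
        for i in range(read.size):
            if read[i] != ref[s + i]:
                mm += 1
                if mm >= best_mm:
                    break
        if mm < best_mm:
            best_mm = mm
            best_start = s
    return best_start, best_mm
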