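"""Numba hot loop for the chi-squared scan over a combinadic interval.

The kernel walks the linear (combinadic) index space incrementally: the
starting tuple is decoded once in Python and each subsequent tuple is
obtained by the O(1)-amortised colexicographic successor, so no binomial
arithmetic happens in the loop.  Cell counts come from AND-ing packed
64-bit genotype words and a SWAR popcount (constant word-level work, no
per-bit iteration).
"""

from __future__ import annotations

import numpy as np
from numba import njit

_M1 = np.uint64(0x5555555555555555)
_M2 = np.uint64(0x3333333333333333)
_M4 = np.uint64(0x0F0F0F0F0F0F0F0F)
_H01 = np.uint64(0x0101010101010101)
_ONE = np.uint64(1)
_TWO = np.uint64(2)
_FOUR = np.uint64(4)
_S56 = np.uint64(56)


@njit(inline="always")
def _popcount64(v):
    v = v - ((v >> _ONE) & _M1)
    v = (v & _M2) + ((v >> _TWO) & _M2)
    v = (v + (v >> _FOUR)) & _M4
    return (v * _H01) >> _S56


@njit(nogil=True, cache=True)
def scan_interval_chi2(
    wc, wx, x0, start, end, score_thresh, out_idx, out_score
):  # pragma: no cover - exercised via run_scan
    """Score tuples with linear indices [start, end) by chi-squared.

    Parameters
    ----------
    wc, wx : (m, 3, W) uint64
        Packed control-class and case-class genotype words.
    x0 : (k,) int64
        The tuple at linear index ``start`` in ascending order
        (x0[0] = x_1 < ... < x0[k-1] = x_k).
    score_thresh : float64
        Keep a tuple iff score >= score_thresh.
    out_idx, out_score
        Preallocated output buffers of length >= end - start.

    Returns
    -------
    (n_kept, err_index) : err_index is the linear index of the first
    degenerate table (empty row marginal) encountered, or -1.
    """
    k = x0.shape[0]
    n_combos = 3**k
    wc_words = wc.shape[2]
    wx_words = wx.shape[2]

    x = x0.copy()
    digits = np.empty(k, dtype=np.int64)
    counts = np.empty((2, n_combos), dtype=np.int64)

    n_kept = 0
    for lin in range(start, end):
        # contingency table: popcount of AND over the k genotype planes
        for j in range(n_combos):
            v = j
            for i in range(k):
                digits[i] = v % 3
                v //= 3
            acc = np.uint64(0)
            s = np.int64(0)
            for w in range(wc_words):
                word = wc[x[0], digits[0], w]
                for i in range(1, k):
                    word &= wc[x[i], digits[i], w]
                s += np.int64(_popcount64(word))
            counts[0, j] = s
            s = np.int64(0)
            for w in range(wx_words):
                word = wx[x[0], digits[0], w]
                for i in range(1, k):
                    word &= wx[x[i], digits[i], w]
                s += np.int64(_popcount64(word))
            counts[1, j] = s

        row0 = np.int64(0)
        row1 = np.int64(0)
        for j in range(n_combos):
            row0 += counts[0, j]
            row1 += counts[1, j]
        n = row0 + row1
        if row0 == 0 or row1 == 0:
            return n_kept, lin

        score = 0.0
        fr0 = float(row0)
        fr1 = float(row1)
        fn = float(n)
        for j in range(n_combos):
            col = counts[0, j] + counts[1, j]
            if col > 0:
                e0 = fr0 * float(col) / fn
                e1 = fr1 * float(col) / fn
                d0 = float(counts[0, j]) - e0
                d1 = float(counts[1, j]) - e1
                score += d0 * d0 / e0 + d1 * d1 / e1

        if score >= score_thresh:
            out_idx[n_kept] = lin
            out_score[n_kept] = score
            n_kept += 1

        # colexicographic successor of the ascending tuple
        for i in range(k):
            if i == k - 1 or x[i] + 1 < x[i + 1]:
                x[i] += 1
                for j2 in range(i):
                    x[j2] = j2
                break

    return n_kept, np.int64(-1)
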