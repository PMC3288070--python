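"""Numba kernels for the two exhaustive scans over the 4^L word space.

Both kernels operate on integer word codes (2 bits per letter, first
letter most significant).  Their contracts are pinned to naive
re-implementations in the test suite; everything here is an
optimisation, not a definition.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, inline="always")
def _within(a: np.int64, b: np.int64, length: int, r: int) -> bool:
    """True iff Hamming distance between codes a and b is <= r (early exit)."""
    d = 0
    x = a ^ b
    for _ in range(length):
        if x & 3:
            d += 1
            if d > r:
                return False
        x >>= 2
    return True


@njit(cache=True)
def greedy_scan(seed_code: np.int64, length: int, min_dist: int) -> np.ndarray:
    """Greedy cyclic vocabulary scan.

    Starting from `seed_code`, every candidate L-mer is visited once in
    alphabetical (numeric) order with wrap-around; a candidate is kept iff
    it differs from every kept word in >= min_dist positions.  Returns the
    kept codes in inclusion order (seed first).
    """
    total = np.int64(1) << np.int64(2 * length)
    out = np.empty(total, dtype=np.int64)
    out[0] = seed_code
    n = 1
    cand = seed_code
    for _ in range(total - 1):
        cand += 1
        if cand == total:
            cand = 0
        ok = True
        for i in range(n):
            x = cand ^ out[i]
            d = 0
            rem = length
            for _ in range(length):
                if x & 3:
                    d += 1
                    if d >= min_dist:
                        break
                x >>= 2
                rem -= 1
                # cannot reach min_dist even if all remaining positions differ
                if d + rem < min_dist:
                    break
            if d < min_dist:
                ok = False
                break
        if ok:
            out[n] = cand
            n += 1
    return out[:n].copy()


@njit(cache=True)
def ball_membership_counts(word_codes: np.ndarray, length: int, r: int) -> np.ndarray:
    """For every L-mer code, the number of vocabulary words within distance r."""
    total = np.int64(1) << np.int64(2 * length)
    counts = np.zeros(total, dtype=np.int32)
    for code in range(total):
        c = 0
        for w in word_codes:
            if _within(np.int64(code), w, length, r):
                c += 1
        counts[code] = c
    return counts


@njit(cache=True)
def fill_ball_membership(word_codes: np.ndarray, length: int, r: int,
                         offsets: np.ndarray, values: np.ndarray) -> None:
    """Fill CSR `values` so values[offsets[c]:offsets[c+1]] lists the word
    indices within distance r of code c, in vocabulary order."""
    total = np.int64(1) << np.int64(2 * length)
    cursor = offsets[:-1].copy()
    for code in range(total):
        for i in range(len(word_codes)):
            if _within(np.int64(code), word_codes[i], length, r):
                values[cursor[code]] = i
                cursor[code] += 1
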