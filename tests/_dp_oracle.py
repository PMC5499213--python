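"""Independent oracles used only by the tests.

``gotoh_full``: a from-scratch, full-matrix (unbanded) affine-gap global
aligner following the package's documented conventions (tie-break diagonal
> gap-consuming-b > gap-consuming-a, gap extension preferred at equal
score, terminal trimming to the maximal-scoring subpath).  It shares no
code with the banded implementation it checks.

``hypergeom_tail``: exact upper-tail hypergeometric probability by direct
enumeration with integer arithmetic.
"""

from fractions import Fraction
from math import comb

import numpy as np
from numba import njit

NEG = -(1 << 40)


@njit(cache=True)
def _fill(a, b, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n = len(a)
    m = len(b)
    H = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    H[0, 0] = 0
    for j in range(1, m + 1):
        E[0, j] = gap_open + gap_extend * j
        H[0, j] = E[0, j]
    for i in range(1, n + 1):
        F[i, 0] = gap_open + gap_extend * i
        H[i, 0] = F[i, 0]
        for j in range(1, m + 1):
            e_open = H[i, j - 1] + gap_open + gap_extend
            e_ext = E[i, j - 1] + gap_extend
            E[i, j] = e_ext if e_ext >= e_open else e_open
            f_open = H[i - 1, j] + gap_open + gap_extend
            f_ext = F[i - 1, j] + gap_extend
            F[i, j] = f_ext if f_ext >= f_open else f_open
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] < 4) else mismatch
            h = H[i - 1, j - 1] + s
            if E[i, j] > h:
                h = E[i, j]
            if F[i, j] > h:
                h = F[i, j]
            H[i, j] = h
    return H, E, F


def gotoh_full(a_codes, b_codes, match=1, mismatch=-2, gap_open=-5, gap_extend=-1):
    """Returns (global_score, segment_score, matches, mismatches, gap_cols)."""
    a = np.ascontiguousarray(a_codes)
    b = np.ascontiguousarray(b_codes)
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        sc = 0 if (n == 0 and m == 0) else gap_open + gap_extend * (n + m)
        return sc, 0, 0, 0, 0
    H, E, F = _fill(a, b, match, mismatch, gap_open, gap_extend)
    # traceback, recovering the same path the implementation prefers
    i, j, state = n, m, "H"
    path = []  # (op, column_score, is_match) from end to start
    while i > 0 or j > 0:
        if state == "H":
            if i > 0 and j > 0:
                s = match if (a[i - 1] == b[j - 1] and a[i - 1] < 4) else mismatch
                if H[i, j] == H[i - 1, j - 1] + s:
                    path.append(("S", s, s == match))
                    i, j = i - 1, j - 1
                    continue
            if H[i, j] == E[i, j]:
                state = "E"
            else:
                state = "F"
            continue
        if state == "E":
            ext = j > 1 and E[i, j] == E[i, j - 1] + gap_extend
            path.append(("B", gap_extend if ext else gap_open + gap_extend, False))
            j -= 1
            state = "E" if ext else "H"
            continue
        ext = i > 1 and F[i, j] == F[i - 1, j] + gap_extend
        path.append(("A", gap_extend if ext else gap_open + gap_extend, False))
        i -= 1
        state = "F" if ext else "H"
    path.reverse()
    # maximal-scoring contiguous subpath (earliest at equal score)
    best, run, start = 0, 0, 0
    b0, b1 = 0, -1
    for idx, (_, sc, _) in enumerate(path):
        run += sc
        if run > best:
            best, b0, b1 = run, start, idx
        if run < 0:
            run, start = 0, idx + 1
    matches = mismatches = gaps = 0
    for op, _, is_m in path[b0 : b1 + 1]:
        if op == "S":
            if is_m:
                matches += 1
            else:
                mismatches += 1
        else:
            gaps += 1
    return int(H[n, m]), int(best), matches, mismatches, gaps


def hypergeom_tail(k: int, K: int, n: int, N: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws)."""
    total = comb(N, n)
    acc = 0
    for x in range(k, min(K, n) + 1):
        if n - x > N - K:
            continue
        acc += comb(K, x) * comb(N - K, n - x)
    return Fraction(acc, total)
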