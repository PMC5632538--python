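"""Independent brute-force oracles shared by unit and acceptance tests.

These deliberately re-derive results with plain loops and literal
definitions; they never call the implementation's internals.
"""

from __future__ import annotations

import math

WC = {("A", "T"), ("U", "A"), ("G", "C"), ("C", "G")}
WOBBLE = {("G", "T"), ("U", "G")}
STOPS = {"TAA", "TAG", "TGA"}

MATCH, WOB, MIS = 5, 2, -3
OPEN, EXT = 8, 2
NEG = -(2**30)


def _sub(q_rev: str, L: int, i: int, tchar: str) -> int:
    """Column score of reversed-miRNA row i (1-based) against a target char."""
    qchar = q_rev[i - 1]
    mir_pos = L - (i - 1)  # 1-based from the miRNA 5' end
    w = 2 if 2 <= mir_pos <= 8 else 1
    if (qchar, tchar) in WC:
        return MATCH * w
    if (qchar, tchar) in WOBBLE:
        return WOB * w
    return MIS * w


def _naive_dp(q_rev: str, L: int, t: str, blocked: list[bool]):
    n = len(t)
    M = [[NEG] * (n + 1) for _ in range(L + 1)]
    Ix = [[NEG] * (n + 1) for _ in range(L + 1)]
    Iy = [[NEG] * (n + 1) for _ in range(L + 1)]
    for i in range(1, L + 1):
        for j in range(1, n + 1):
            prev = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1], 0)
            M[i][j] = _sub(q_rev, L, i, t[j - 1]) + prev
            Ix[i][j] = max(M[i - 1][j] - OPEN, Ix[i - 1][j] - EXT)
            Iy[i][j] = max(M[i][j - 1] - OPEN, Iy[i][j - 1] - EXT)
            if blocked[j - 1]:
                M[i][j] = NEG
                Iy[i][j] = NEG
    return M, Ix, Iy


def _traceback(q_rev, L, t, M, Ix, Iy, i, j):
    cols = []
    state = "M"
    while i > 0 and j > 0:
        if state == "M":
            if M[i][j] <= NEG // 2:
                break
            cols.append((i, j, "sub"))
            prev = M[i][j] - _sub(q_rev, L, i, t[j - 1])
            i, j = i - 1, j - 1
            if prev == 0 and max(M[i][j], Ix[i][j], Iy[i][j]) < 0:
                break
            if M[i][j] == prev:
                state = "M"
            elif Ix[i][j] == prev:
                state = "Ix"
            elif Iy[i][j] == prev:
                state = "Iy"
            else:
                break
        elif state == "Ix":
            cols.append((i, j, "gap_t"))
            if M[i - 1][j] - OPEN == Ix[i][j]:
                state = "M"
            i -= 1
        else:
            cols.append((i, j, "gap_q"))
            if M[i][j - 1] - OPEN == Iy[i][j]:
                state = "M"
            j -= 1
    cols.reverse()
    return cols


def _pair_class(qchar: str, tchar: str) -> int:
    if (qchar, tchar) in WC:
        return 2 if {qchar, tchar} <= {"G", "C"} else 1
    if (qchar, tchar) in WOBBLE:
        return 3
    return 0


def _energy(q_rev: str, t: str, cols) -> float:
    classes = [
        _pair_class(q_rev[i - 1], t[j - 1]) if kind == "sub" else -1
        for i, j, kind in cols
    ]
    e = 0.0
    for a, b in zip(classes, classes[1:]):
        if a <= 0 or b <= 0:
            continue
        if a == 3 or b == 3:
            e += -1.0
        elif a == 2 and b == 2:
            e += -3.3
        elif a == 1 and b == 1:
            e += -1.1
        else:
            e += -2.1
    return e


def naive_scan(mirna_seq: str, region_seq: str, score_min: float, energy_max: float):
    """Greedy non-overlapping site extraction with plain-loop DP.

    Returns retained sites as (start, end, score, energy) tuples sorted by
    (-score, start) -- the same contract as the implementation.
    """
    q = mirna_seq.upper().replace("T", "U")
    q_rev = q[::-1]
    L = len(q)
    t = region_seq.upper()
    blocked = [False] * len(t)
    out = []
    while True:
        M, Ix, Iy = _naive_dp(q_rev, L, t, blocked)
        best, bi, bj = NEG, -1, -1
        for j in range(1, len(t) + 1):  # leftmost end, then smallest row
            for i in range(1, L + 1):
                if M[i][j] > best:
                    best, bi, bj = M[i][j], i, j
        if best <= score_min:
            break
        cols = _traceback(q_rev, L, t, M, Ix, Iy, bi, bj)
        if not cols:
            break
        tpos = [j - 1 for _i, j, kind in cols if kind != "gap_t"]
        start, end = min(tpos), max(tpos) + 1
        for k in range(start, end):
            blocked[k] = True
        energy = _energy(q_rev, t, cols)
        if energy < energy_max:
            out.append((start, end, float(best), energy))
    return sorted(out, key=lambda s: (-s[2], s[0]))


def hypergeom_tail_oracle(overlap: int, n_universe: int, n_category: int, n_query: int) -> float:
    """P[X >= overlap] by literal summation of the hypergeometric pmf."""
    total = math.comb(n_universe, n_query)
    p = 0.0
    for k in range(overlap, min(n_category, n_query) + 1):
        if n_query - k > n_universe - n_category:
            continue
        p += math.comb(n_category, k) * math.comb(n_universe - n_category, n_query - k) / total
    return p
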