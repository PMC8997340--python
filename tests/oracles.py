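"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive and shares no code with the package:
a Gotoh affine-gap DP for alignment scores, exhaustive enumeration of
nested secondary structures, and a three-sequence sum-of-pairs alignment
DP for the multiple-alignment bound.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

NEG = float("-inf")


def gotoh_score(a: str, b: str, sub, gap_open: float, gap_extend: float, local: bool) -> float:
    """Optimal alignment score with gap cost open + extend*L.

    ``sub(x, y)`` is the substitution score. Plain three-state Gotoh.
    """
    n, m = len(a), len(b)
    first = gap_open + gap_extend  # cost of opening a length-1 gap
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (a consumed)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    best_local = 0.0
    for i in range(n + 1):
        for j in range(m + 1):
            if i > 0:
                X[i][j] = max(M[i - 1][j] - first, X[i - 1][j] - gap_extend)
            if j > 0:
                Y[i][j] = max(M[i][j - 1] - first, Y[i][j - 1] - gap_extend)
            if i > 0 and j > 0:
                diag = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
                if local:
                    diag = max(diag, 0.0)
                M[i][j] = diag + sub(a[i - 1], b[j - 1])
            elif i == 0 and j == 0:
                M[i][j] = 0.0
            if local:
                best_local = max(best_local, M[i][j] if M[i][j] != NEG else 0.0)
    if local:
        return best_local
    return max(M[n][m], X[n][m], Y[n][m])


def enumerate_structures(n: int, min_loop: int = 3) -> list[tuple[tuple[int, int], ...]]:
    """All nested pair sets over n positions with hairpin loops >= min_loop."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> tuple[tuple[tuple[int, int], ...], ...]:
        if j - i <= min_loop:
            return ((),)
        out = list(rec(i + 1, j))
        for k in range(i + min_loop + 1, j + 1):
            for inner in rec(i + 1, k - 1):
                for right in rec(k + 1, j):
                    out.append(((i, k),) + inner + right)
        return tuple(out)

    result = list(rec(0, n - 1))
    rec.cache_clear()
    return result


PAIR_WEIGHTS = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "U"): 2, ("U", "A"): 2, ("A", "T"): 2, ("T", "A"): 2,
    ("G", "U"): 1, ("U", "G"): 1, ("G", "T"): 1, ("T", "G"): 1,
}


def structure_weight(seq: str, pairs) -> int:
    return sum(PAIR_WEIGHTS.get((seq[i], seq[j]), 0) for i, j in pairs)


def max_weight_by_enumeration(seq: str, min_loop: int = 3, structures=None) -> int:
    structures = structures if structures is not None else enumerate_structures(len(seq), min_loop)
    return max(structure_weight(seq, s) for s in structures)


def sp_cost_msa(rows: list[str]) -> int:
    """Unit-cost sum-of-pairs cost of an alignment (gap-gap costs 0)."""
    cost = 0
    for a, b in itertools.combinations(rows, 2):
        for x, y in zip(a, b):
            if x == "-" and y == "-":
                continue
            if x == "-" or y == "-" or x != y:
                cost += 1
    return cost


def optimal_sp_cost_3(s1: str, s2: str, s3: str) -> int:
    """Optimal unit-cost SP alignment of three sequences (cubic DP)."""
    n1, n2, n3 = len(s1), len(s2), len(s3)
    INF = float("inf")

    def pair_cost(x, y):
        if x is None and y is None:
            return 0
        if x is None or y is None:
            return 1
        return 0 if x == y else 1

    dp = [[[INF] * (n3 + 1) for _ in range(n2 + 1)] for _ in range(n1 + 1)]
    dp[0][0][0] = 0
    for i in range(n1 + 1):
        for j in range(n2 + 1):
            for k in range(n3 + 1):
                cur = dp[i][j][k]
                if cur == INF:
                    continue
                for di, dj, dk in itertools.product((0, 1), repeat=3):
                    if di + dj + dk == 0:
                        continue
                    ni, nj, nk = i + di, j + dj, k + dk
                    if ni > n1 or nj > n2 or nk > n3:
                        continue
                    x = s1[i] if di else None
                    y = s2[j] if dj else None
                    z = s3[k] if dk else None
                    step = pair_cost(x, y) + pair_cost(x, z) + pair_cost(y, z)
                    if cur + step < dp[ni][nj][nk]:
                        dp[ni][nj][nk] = cur + step
    return int(dp[n1][n2][n3])
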