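"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (exhaustive enumeration, direct
formula evaluation) and shares no code path with the package's dynamic
programming or scipy-backed statistics.
"""
from __future__ import annotations

import itertools
import re
from functools import lru_cache

ALLOWED = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def _rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def enumerate_structures(seq: str, min_loop: int = 3) -> list[tuple[tuple[int, int], ...]]:
    """All valid non-crossing pair sets (1-based pairs), incl. the open chain."""
    s = _rna(seq)
    n = len(s)

    @lru_cache(maxsize=None)
    def enum(i: int, j: int) -> tuple[tuple[tuple[int, int], ...], ...]:
        if j - i < min_loop + 1:
            return ((),)
        out = list(enum(i + 1, j))  # i unpaired
        for k in range(i + min_loop + 1, j + 1):
            if (s[i], s[k]) in ALLOWED:
                lefts = enum(i + 1, k - 1)
                rights = enum(k + 1, j) if k < j else ((),)
                for left in lefts:
                    for right in rights:
                        out.append(left + ((i + 1, k + 1),) + right)
        return tuple(out)

    result = enum(0, n - 1)
    enum.cache_clear()
    return list(result)


def brute_max_pairs(seq: str, min_loop: int = 3) -> int:
    return max(len(s) for s in enumerate_structures(seq, min_loop))


def hairpin_count_from_dotbracket(dotbracket: str) -> int:
    """Hairpin loops counted as '(' dots* ')' adjacencies in the string."""
    return len(re.findall(r"\(\.*\)", dotbracket))


def mann_whitney_exact_p(x, y, alternative: str = "two_sided") -> float:
    """Exact p by full enumeration of all C(n+m, n) group labelings."""
    pooled = list(x) + list(y)
    n, N = len(x), len(pooled)
    order = sorted(range(N), key=lambda i: pooled[i])
    ranks = [0.0] * N
    i = 0
    while i < N:  # midranks
        j = i
        while j + 1 < N and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        for k in range(i, j + 1):
            ranks[order[k]] = (i + j) / 2 + 1
        i = j + 1
    u_obs = sum(ranks[:n]) - n * (n + 1) / 2
    us = []
    for combo in itertools.combinations(range(N), n):
        us.append(sum(ranks[i] for i in combo) - n * (n + 1) / 2)
    total = len(us)
    eps = 1e-9
    p_le = sum(1 for u in us if u <= u_obs + eps) / total
    p_ge = sum(1 for u in us if u >= u_obs - eps) / total
    if alternative == "less":
        return min(1.0, p_le)
    if alternative == "greater":
        return min(1.0, p_ge)
    return min(1.0, 2 * min(p_le, p_ge))


def kruskal_h(groups) -> float:
    """Direct evaluation of H = 12/(N(N+1)) * sum n_i (Rbar_i - Rbar)^2 (no ties)."""
    pooled = [v for g in groups for v in g]
    N = len(pooled)
    ranks = {v: r + 1 for r, v in enumerate(sorted(pooled))}
    h = 0.0
    for g in groups:
        rbar = sum(ranks[v] for v in g) / len(g)
        h += len(g) * (rbar - (N + 1) / 2) ** 2
    return 12.0 / (N * (N + 1)) * h
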