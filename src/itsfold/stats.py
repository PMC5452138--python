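"""Rank-based group comparisons and descriptive summaries.

Policy for the Mann-Whitney p-value:

* exact enumeration of the U null distribution when the pooled sample is
  small (n + m <= 25) and tie-free;
* seeded Monte-Carlo permutation (default 100,000 draws) when the pooled
  sample is small but tied;
* normal approximation with tie and continuity corrections otherwise.

The Kruskal-Wallis H statistic is tie-corrected with a chi-square
reference distribution (k - 1 df).  No multiple-testing correction is
applied by default (raw p-values are reported); a Holm adjustment helper
is provided for callers who want one.
"""
from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import stats as sps

Alternative = Literal["two_sided", "less", "greater"]

_SCIPY_ALT = {"two_sided": "two-sided", "less": "less", "greater": "greater"}

#: pooled-size threshold below which small-sample p methods are used
EXACT_LIMIT = 25


@dataclass
class TestResult:
    method: str                  # "mann_whitney" | "kruskal_wallis"
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]
    ties_present: bool
    p_method: str                # exact | permutation | normal_approx | chi_square
    effect_size: Optional[float] = None  # rank-biserial (Mann-Whitney only)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # midranks
    n = len(x)
    u = float(ranks[:n].sum() - n * (n + 1) / 2)
    ties = len(np.unique(pooled)) < len(pooled)
    return u, ties


def _permutation_p(
    x: np.ndarray, y: np.ndarray, u_obs: float, alternative: Alternative,
    n_permutations: int, seed: int,
) -> float:
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([x, y])
    n, N = len(x), len(pooled)
    ranks = sps.rankdata(pooled)
    draws = np.empty(n_permutations)
    block = 20_000
    done = 0
    while done < n_permutations:
        b = min(block, n_permutations - done)
        idx = np.argsort(rng.random((b, N)), axis=1)[:, :n]
        draws[done : done + b] = ranks[idx].sum(axis=1) - n * (n + 1) / 2
        done += b
    eps = 1e-9
    p_le = (np.count_nonzero(draws <= u_obs + eps) + 1) / (n_permutations + 1)
    p_ge = (np.count_nonzero(draws >= u_obs - eps) + 1) / (n_permutations + 1)
    if alternative == "less":
        return min(1.0, p_le)
    if alternative == "greater":
        return min(1.0, p_ge)
    return min(1.0, 2 * min(p_le, p_ge))


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    alternative: Alternative = "two_sided",
    n_permutations: int = 100_000,
    seed: int = 0,
) -> TestResult:
    """Wilcoxon-Mann-Whitney rank-sum test (U of the first sample).

    ``alternative="greater"`` tests whether values in ``x`` tend to exceed
    those in ``y``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    u, ties = _u_statistic(x, y)
    n, m = len(x), len(y)
    effect = 1.0 - 2.0 * u / (n * m)  # rank-biserial correlation (y-favoured > 0)

    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("constant pooled data: p set to 1", stacklevel=2)
        return TestResult("mann_whitney", u, 1.0, (n, m), True, "degenerate", 0.0)

    if n + m <= EXACT_LIMIT and not ties:
        res = sps.mannwhitneyu(x, y, alternative=_SCIPY_ALT[alternative], method="exact")
        p, p_method = float(res.pvalue), "exact"
    elif n + m <= EXACT_LIMIT:
        p = _permutation_p(x, y, u, alternative, n_permutations, seed)
        p_method = "permutation"
    else:
        res = sps.mannwhitneyu(
            x, y, alternative=_SCIPY_ALT[alternative], method="asymptotic",
            use_continuity=True,
        )
        p, p_method = float(res.pvalue), "normal_approx"
    return TestResult("mann_whitney", u, min(p, 1.0), (n, m), ties, p_method, effect)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H test with tie correction, chi-square p (k-1 df)."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("all groups must be non-empty")
    ns = tuple(len(a) for a in arrays)
    pooled = np.concatenate(arrays)
    ties = len(np.unique(pooled)) < len(pooled)
    if np.all(pooled == pooled[0]):
        warnings.warn("constant pooled data: H = 0, p = 1", stacklevel=2)
        return TestResult("kruskal_wallis", 0.0, 1.0, ns, True, "degenerate")
    h, p = sps.kruskal(*arrays)
    return TestResult("kruskal_wallis", float(h), float(p), ns, ties, "chi_square")


@dataclass
class GroupSummary:
    label: str
    n: int
    mean: float
    sd: float
    min: float
    max: float
    mode: float


def describe(values: Sequence[float], label: str = "") -> GroupSummary:
    """Mean, sample SD (n-1; 0 when n = 1), min, max and smallest mode."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("describe needs at least one value")
    counts = Counter(arr.tolist())
    top = max(counts.values())
    mode = min(v for v, c in counts.items() if c == top)
    return GroupSummary(
        label=label,
        n=int(arr.size),
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        min=float(arr.min()),
        max=float(arr.max()),
        mode=float(mode),
    )


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjustment (optional; raw p-values are the default)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted.tolist()
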