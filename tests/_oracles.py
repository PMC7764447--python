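"""Independent brute-force oracles used by the test suite.

Each oracle is deliberately naive (enumeration, exact rational arithmetic,
direct formula evaluation) and shares no code path with the implementation
it checks.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations

import numpy as np


def hypergeom_tail_enumeration(k: int, K: int, n: int, N: int) -> Fraction:
    """P(X >= k) by literally enumerating all C(N, n) draws.

    The population is range(N) with the first K elements marked as
    successes.  Exact rational arithmetic; only feasible for small N.
    """
    marked = set(range(K))
    hits = 0
    total = 0
    for draw in combinations(range(N), n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return Fraction(hits, total)


def hypergeom_tail_histograms(N: int, n: int) -> dict[int, list[int]]:
    """For each K, the overlap-size histogram over all C(N, n) draws.

    Returns ``hist[K][j]`` = number of draws with |draw ∩ first K| = j.
    One enumeration pass serves every K (bitmask prefix counting).
    """
    hists = {K: [0] * (n + 1) for K in range(N + 1)}
    for draw in combinations(range(N), n):
        mask = 0
        for d in draw:
            mask |= 1 << d
        for K in range(N + 1):
            j = (mask & ((1 << K) - 1)).bit_count()
            hists[K][j] += 1
    return hists


def hypergeom_tail_rational(k: int, K: int, n: int, N: int) -> Fraction:
    """P(X >= k) by the exact combinatorial sum in big-rational arithmetic."""
    total = math.comb(N, n)
    hits = sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k, min(K, n) + 1)
        if n - j <= N - K
    )
    return Fraction(hits, total)


def bh_stepup_by_hand(p_values) -> list[float]:
    """Benjamini-Hochberg by the literal step-up definition.

    adjusted[i] = min over ranks j >= rank(i) of m * p_(j) / j, clipped at 1.
    """
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running = 1.0
    for pos in range(m - 1, -1, -1):
        i = order[pos]
        rank = pos + 1
        running = min(running, m * p_values[i] / rank)
        adjusted[i] = min(running, 1.0)
    return adjusted


def pearson_by_hand(x, y) -> float:
    """Pearson r by direct evaluation of the definition."""
    x = list(map(float, x))
    y = list(map(float, y))
    m = len(x)
    mx = sum(x) / m
    my = sum(y) / m
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def pearson_pvalue_by_hand(r: float, m: int) -> float:
    """Two-sided p from t = r sqrt((m-2)/(1-r^2)) on m-2 df."""
    from scipy.stats import t as tdist

    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt((m - 2) / (1.0 - r * r))
    return 2.0 * tdist.sf(abs(t), m - 2)


def ap_net_similarity(S: np.ndarray, exemplars) -> float:
    """Net similarity of an exemplar set: preferences plus best assignments."""
    exemplars = list(exemplars)
    net = sum(S[e, e] for e in exemplars)
    for i in range(S.shape[0]):
        if i not in exemplars:
            net += max(S[i, e] for e in exemplars)
    return float(net)


def ap_brute_force_optimum(S: np.ndarray) -> tuple[float, tuple[int, ...]]:
    """Exhaustive search over all non-empty exemplar subsets."""
    m = S.shape[0]
    best = (-math.inf, ())
    for mask in range(1, 1 << m):
        subset = tuple(i for i in range(m) if mask >> i & 1)
        net = ap_net_similarity(S, subset)
        if net > best[0]:
            best = (net, subset)
    return best
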