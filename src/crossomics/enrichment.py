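"""Over-representation analysis (ORA) and exemplar-based term reduction.

Each gene set of a GMT collection is tested for enrichment in a query list
with the one-sided hypergeometric test against the protein-coding universe
(``referenceSet = genome`` convention), adjusted across the collection with
Benjamini-Hochberg, and annotated with the enrichment ratio
(k/n) / (K/N).

Because flat ORA of a large GO branch typically yields dozens of highly
redundant significant terms, the significant set can be reduced to
representative exemplars by affinity propagation over a term-term similarity
matrix (Jaccard index of member genes restricted to the universe, preference
= median off-diagonal similarity).  The message-passing updates are the
classic responsibility/availability scheme:

    r(i,k) <- s(i,k) - max_{k' != k} [a(i,k') + s(i,k')]
    a(i,k) <- min(0, r(k,k) + sum_{i' not in {i,k}} max(0, r(i',k)))  (i != k)
    a(k,k) <- sum_{i' != k} max(0, r(i',k))

with damped updates; exemplars are the points with r(k,k) + a(k,k) > 0
after convergence.  No symmetric noise is injected to break ties (some
implementations do); ties resolve deterministically to the lower term index,
trading convergence-speed folklore for reproducibility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .io_model import GeneSetCollection, normalize_symbol
from .overlap import hypergeom_pvalue

logger = logging.getLogger(__name__)

DEFAULT_DAMPING = 0.9
DEFAULT_MAX_ITER = 1000
DEFAULT_CONV_ITER = 100


@dataclass(frozen=True)
class EnrichmentResult:
    """One ORA row: term, counts, p, BH-FDR, enrichment ratio, exemplar flag."""

    term: str
    k: int
    K: int
    n: int
    N: int
    p_value: float
    bh_fdr: float
    enrichment_ratio: float
    significant: bool
    is_exemplar: bool = False
    exemplar: Optional[str] = None


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, order-preserving.

    adjusted[i] = min over the tail of (m * p / rank), clipped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return [float(q) for q in multipletests(p, method="fdr_bh")[1]]


def ora(
    query: Iterable[str],
    collection: GeneSetCollection,
    fdr_threshold: float = 0.05,
    background: Optional[Iterable[str]] = None,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of ``query`` in every set.

    The universe is the collection's population (the protein-coding genome)
    unless an explicit ``background`` is given; the query and all member
    sets are restricted to it first.  BH adjustment runs across all sets of
    the collection; ``significant`` means bh_fdr <= fdr_threshold.  Results
    are sorted by p ascending, ties by term name.
    """
    if background is not None:
        uni = frozenset(normalize_symbol(g) for g in background)
    elif collection.universe is not None:
        uni = collection.universe
    else:
        raise ValueError("no universe: give the collection one or pass background=")
    query_set = frozenset(normalize_symbol(g) for g in query) & uni
    n = len(query_set)
    if n == 0:
        raise ValueError("query has no genes inside the universe")
    N = len(uni)

    rows = []
    for name in sorted(collection.sets):
        members = collection.sets[name].members & uni
        K = len(members)
        k = len(query_set & members)
        p = hypergeom_pvalue(k, K, n, N) if K else 1.0
        ratio = (k / n) / (K / N) if K else 0.0
        rows.append((name, k, K, p, ratio))
    adjusted = bh_adjust([r[3] for r in rows])
    results = [
        EnrichmentResult(
            term=name,
            k=k,
            K=K,
            n=n,
            N=N,
            p_value=p,
            bh_fdr=q,
            enrichment_ratio=ratio,
            significant=q <= fdr_threshold,
        )
        for (name, k, K, p, ratio), q in zip(rows, adjusted)
    ]
    results.sort(key=lambda r: (r.p_value, r.term))
    return results


@dataclass
class TermSimilarity:
    """Symmetric term-term similarity with the preference on the diagonal."""

    terms: tuple[str, ...]
    matrix: np.ndarray
    preference: float


def _pairwise_similarity(
    members: list[frozenset[str]], metric: str = "jaccard"
) -> np.ndarray:
    m = len(members)
    S = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            inter = len(members[i] & members[j])
            if metric == "jaccard":
                denom = len(members[i] | members[j])
            elif metric == "overlap-coef":
                denom = min(len(members[i]), len(members[j]))
            else:
                raise ValueError(f"unknown similarity metric {metric!r}")
            S[i, j] = S[j, i] = inter / denom if denom else 0.0
    return S


def term_similarity(
    terms: Sequence[str],
    collection: GeneSetCollection,
    metric: str = "jaccard",
) -> TermSimilarity:
    """Similarity matrix over terms; diagonal set to the median off-diagonal."""
    uni = collection.universe
    members = [
        collection.sets[t].members & uni if uni is not None else collection.sets[t].members
        for t in terms
    ]
    S = _pairwise_similarity(members, metric)
    m = len(terms)
    if m > 1:
        off = S[~np.eye(m, dtype=bool)]
        preference = float(np.median(off))
    else:
        preference = 1.0
    np.fill_diagonal(S, preference)
    return TermSimilarity(terms=tuple(terms), matrix=S, preference=preference)


@dataclass
class APResult:
    """Affinity-propagation output: exemplar indices, point assignment."""

    exemplars: list[int]
    assignment: list[int]
    converged: bool
    n_iter: int


def _net_similarity(S: np.ndarray, exemplars: Sequence[int]) -> float:
    """Sum of exemplar preferences plus each point's best exemplar similarity."""
    ex = list(exemplars)
    net = sum(S[e, e] for e in ex)
    for i in range(S.shape[0]):
        if i not in ex:
            net += max(S[i, e] for e in ex)
    return float(net)


def _tied_exemplars(S: np.ndarray) -> list[int]:
    """Deterministic exemplar choice when the evidence is fully tied.

    Small inputs: exhaustive net-similarity search over all subsets.  Net
    ties prefer more exemplars (an unrepresented point stays its own
    exemplar), then lower indices.  Larger inputs fall back to forward
    greedy selection with the same tie rule.
    """
    m = S.shape[0]
    if m <= 15:
        best: list[int] = []
        best_net = -np.inf
        for mask in range(1, 1 << m):
            subset = [i for i in range(m) if mask >> i & 1]
            net = _net_similarity(S, subset)
            if net > best_net + 1e-12 or (
                net >= best_net - 1e-12 and len(subset) > len(best)
            ):
                best, best_net = subset, max(net, best_net)
        return best
    singles = [S[k, k] + sum(S[i, k] for i in range(m) if i != k) for k in range(m)]
    exemplars = [int(np.argmax(singles))]
    current = _net_similarity(S, exemplars)
    improved = True
    while improved:
        improved = False
        for k in range(m):
            if k in exemplars:
                continue
            candidate = _net_similarity(S, exemplars + [k])
            if candidate >= current - 1e-12:
                exemplars = sorted(exemplars + [k])
                current = max(candidate, current)
                improved = True
    return exemplars


def affinity_propagation(
    S: np.ndarray,
    damping: float = DEFAULT_DAMPING,
    max_iter: int = DEFAULT_MAX_ITER,
    conv_iter: int = DEFAULT_CONV_ITER,
) -> APResult:
    """Exemplar selection by responsibility/availability message passing.

    ``S`` is a square similarity matrix whose diagonal already carries the
    preference.  Convergence is declared when the exemplar indicator vector
    is unchanged for ``conv_iter`` consecutive iterations.  If no diagonal
    evidence is positive at the end, the single point with the largest
    evidence becomes the exemplar, so the result is always usable.
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("similarity matrix must be square")
    off = ~np.eye(S.shape[0], dtype=bool)
    if not np.allclose(S[off], S.T[off]):
        raise ValueError("similarity matrix must be symmetric off the diagonal")
    if not 0.5 <= damping < 1:
        raise ValueError("damping must lie in [0.5, 1)")
    m = S.shape[0]
    if m == 1:
        return APResult(exemplars=[0], assignment=[0], converged=True, n_iter=0)

    R = np.zeros((m, m))
    A = np.zeros((m, m))
    idx = np.arange(m)
    stable = 0
    last_indicator = None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # responsibilities
        AS = A + S
        first_k = AS.argmax(axis=1)
        first_v = AS[idx, first_k]
        AS[idx, first_k] = -np.inf
        second_v = AS.max(axis=1)
        Rnew = S - first_v[:, None]
        Rnew[idx, first_k] = S[idx, first_k] - second_v
        R = damping * R + (1 - damping) * Rnew
        # availabilities
        Rp = np.maximum(R, 0)
        Rp[idx, idx] = R[idx, idx]
        colsum = Rp.sum(axis=0)
        Anew = np.minimum(0, colsum[None, :] - Rp)
        Anew[idx, idx] = colsum - R[idx, idx]
        A = damping * A + (1 - damping) * Anew

        indicator = (np.diag(R) + np.diag(A)) > 0
        if last_indicator is not None and np.array_equal(indicator, last_indicator):
            stable += 1
            if stable >= conv_iter and indicator.any():
                converged = True
                break
        else:
            stable = 0
        last_indicator = indicator

    evidence = np.diag(R) + np.diag(A)
    # evidence that converged to 0 up to round-off is a tie, not a choice
    tol = 1e-9 * max(1.0, float(np.abs(S).max()))
    exemplars = [int(i) for i in np.flatnonzero(evidence > tol)]
    if not exemplars:
        # Degenerate tie: with exactly symmetric inputs (e.g. duplicated
        # terms) the evidence converges to 0 for every candidate and no
        # strict exemplar emerges.  Resolve deterministically by greedy net-
        # similarity maximization scanning candidates in index order, so the
        # lower index wins among equivalent points.
        exemplars = _tied_exemplars(S)
        logger.warning(
            "no positive exemplar evidence (tied candidates); resolved "
            "deterministically to %s", exemplars,
        )
    if not converged:
        logger.warning("affinity propagation did not converge in %d iterations", max_iter)
    ex = np.array(exemplars)
    # argmax resolves similarity ties to the lower exemplar index
    assignment = [int(ex[np.argmax(S[i, ex])]) for i in range(m)]
    for e in exemplars:
        assignment[e] = e
    return APResult(exemplars=exemplars, assignment=assignment, converged=converged, n_iter=it)


def reduce_terms(
    results: Sequence[EnrichmentResult],
    collection: GeneSetCollection,
    metric: str = "jaccard",
    damping: float = DEFAULT_DAMPING,
    max_iter: int = DEFAULT_MAX_ITER,
    conv_iter: int = DEFAULT_CONV_ITER,
) -> list[EnrichmentResult]:
    """Flag representative exemplars among the significant ORA terms.

    Builds the Jaccard term similarity (preference = median off-diagonal),
    runs affinity propagation, and returns all input rows with
    ``is_exemplar`` set and each significant term's exemplar recorded.
    Term order does not affect the outcome: terms are processed in sorted
    name order.
    """
    significant = [r for r in results if r.significant]
    if not significant:
        return list(results)
    uni = collection.universe
    # exact-duplicate member sets collapse to the alphabetically first term;
    # the duplicates inherit its exemplar afterwards
    by_members: dict[frozenset, list[str]] = {}
    for name in sorted(r.term for r in significant):
        members = collection.sets[name].members
        if uni is not None:
            members = members & uni
        by_members.setdefault(members, []).append(name)
    reps = sorted(names[0] for names in by_members.values())
    if len(reps) == 1:
        rep_map = {reps[0]: reps[0]}
    else:
        sim = term_similarity(reps, collection, metric=metric)
        ap = affinity_propagation(sim.matrix, damping, max_iter, conv_iter)
        rep_map = {reps[i]: reps[ap.assignment[i]] for i in range(len(reps))}
    mapping = {
        name: rep_map[names[0]]
        for names in by_members.values()
        for name in names
    }
    out = []
    for r in results:
        if r.term in mapping:
            out.append(
                replace(r, is_exemplar=mapping[r.term] == r.term, exemplar=mapping[r.term])
            )
        else:
            out.append(r)
    return out
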