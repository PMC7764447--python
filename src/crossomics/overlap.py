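"""Set-overlap statistics between conditions (or omics layers).

Two views of the same input sets are computed:

* the exclusive Venn partition (each gene assigned to exactly one region,
  the region of all sets that contain it), and
* full pairwise intersections tested for enrichment with a one-sided
  hypergeometric test against a fixed gene population.

The hypergeometric upper tail includes the observed overlap: for sets of
sizes K and n drawn from a population of N symbols, the p-value is
P(X >= k) with X ~ Hypergeom(N, K, n).  scipy evaluates the tail in
log-space, which survives N ~ 2e4 without underflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Optional

from scipy.stats import hypergeom

#: population size of the protein-coding symbol universe used as default N
DEFAULT_POPULATION_SIZE = 19324


@dataclass(frozen=True)
class OverlapTest:
    """One pairwise overlap with its hypergeometric parameters."""

    label: tuple[str, ...]
    k: int
    K: int
    n: int
    N: int
    p_value: float
    bh_fdr: Optional[float] = None


@dataclass
class VennPartition:
    """Exclusive-region decomposition of 2-6 labelled sets.

    ``regions`` maps every non-empty label subset (as a sorted tuple) to the
    genes belonging to exactly those sets; regions are pairwise disjoint and
    cover the union of the inputs.
    """

    set_labels: tuple[str, ...]
    regions: dict[tuple[str, ...], frozenset[str]] = field(default_factory=dict)

    def region(self, *labels: str) -> frozenset[str]:
        return self.regions[tuple(sorted(labels))]

    @property
    def full_intersection(self) -> frozenset[str]:
        """Genes present in all input sets (the Venn centre)."""
        return self.regions[tuple(sorted(self.set_labels))]


def venn_partition(sets: Mapping[str, Iterable[str]]) -> VennPartition:
    """Decompose labelled gene sets into exclusive Venn regions.

    For m sets all 2^m - 1 regions are materialized (possibly empty); every
    input gene lands in exactly one region.
    """
    labels = tuple(sets.keys())
    if not 2 <= len(labels) <= 6:
        raise ValueError(f"need 2-6 sets, got {len(labels)}")
    fsets = {lab: frozenset(sets[lab]) for lab in labels}
    membership: dict[str, tuple[str, ...]] = {}
    for gene in frozenset().union(*fsets.values()):
        membership[gene] = tuple(sorted(lab for lab in labels if gene in fsets[lab]))
    regions = {
        tuple(sorted(combo)): frozenset()
        for r in range(1, len(labels) + 1)
        for combo in combinations(labels, r)
    }
    grouped: dict[tuple[str, ...], set[str]] = {}
    for gene, key in membership.items():
        grouped.setdefault(key, set()).add(gene)
    for key, genes in grouped.items():
        regions[key] = frozenset(genes)
    return VennPartition(set_labels=labels, regions=regions)


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k), observed k included.

    Parameters are the overlap size k, the two set sizes K and n, and the
    population size N.  k = 0 is the whole sample space (p = 1).
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"set sizes K={K}, n={n} must lie in [0, N={N}]")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"overlap k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    # sf(k-1) = P(X > k-1) = P(X >= k); scipy works on log gamma internally.
    # Extreme overlaps underflow double precision; clamp to the smallest
    # positive float so the p-value stays in (0, 1].
    p = float(hypergeom.sf(k - 1, N, K, n))
    return p if p > 0.0 else 5e-324


def pairwise_overlap_tests(
    sets: Mapping[str, Iterable[str]],
    N: int = DEFAULT_POPULATION_SIZE,
    universe: Optional[Iterable[str]] = None,
    strict: bool = False,
) -> list[OverlapTest]:
    """Hypergeometric enrichment test for every unordered pair of sets.

    Uses the full pairwise intersection k = |A ∩ B| (not the exclusive Venn
    region).  When ``universe`` is given its cardinality overrides ``N`` and,
    in strict mode, any symbol outside it raises.  Results are sorted by
    p-value ascending with a stable tie order by label.  A BH-adjusted column
    across the pairs is attached for convenience; the primary statistic is
    the raw hypergeometric p.
    """
    fsets = {lab: frozenset(sets[lab]) for lab in sets}
    if universe is not None:
        uni = frozenset(universe)
        N = len(uni)
        if strict:
            for lab, s in fsets.items():
                stray = s - uni
                if stray:
                    raise ValueError(
                        f"set {lab!r} has {len(stray)} symbols outside the "
                        f"population, e.g. {sorted(stray)[:5]}"
                    )
    for lab, s in fsets.items():
        if len(s) > N:
            raise ValueError(f"set {lab!r} larger than population N={N}")

    tests = []
    for a, b in combinations(fsets, 2):
        k = len(fsets[a] & fsets[b])
        tests.append(
            OverlapTest(
                label=(a, b),
                k=k,
                K=len(fsets[a]),
                n=len(fsets[b]),
                N=N,
                p_value=hypergeom_pvalue(k, len(fsets[a]), len(fsets[b]), N),
            )
        )
    tests.sort(key=lambda t: (t.p_value, t.label))
    # BH across the pairs, clearly secondary to the raw p-values
    from .enrichment import bh_adjust

    adjusted = bh_adjust([t.p_value for t in tests])
    return [
        OverlapTest(t.label, t.k, t.K, t.n, t.N, t.p_value, bh_fdr=q)
        for t, q in zip(tests, adjusted)
    ]
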