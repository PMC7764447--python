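"""Direction-of-regulation concordance between conditions.

For each gene surviving the cascade in a condition and layer, the mean
direction of regulation is the average of the regulation signs over its
significant appearances:

    MeanRegDir(gene) = (1/n) * sum_i sig(effect_i),   sig(x) = +1 if x > 0,
                                                               -1 if x < 0,

with n the number of studies in which the gene passed the FDR threshold.
The value lies in [-1, 1]; |MeanRegDir| = 1 exactly when all studies agree
on the direction.  An effect of exactly 0 has no sign and is excluded from
both the numerator and n.

Conditions are then compared over a common gene set (typically the
all-conditions intersection) by Pearson correlation with the t-distribution
p-value (the default of R's cor.test), and clustered hierarchically on the
gene x condition matrix with Euclidean distance and complete linkage (the
defaults of the pheatmap-style heatmap workflow).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import pearsonr

from .io_model import DEGRecord

logger = logging.getLogger(__name__)


def mean_reg_dir(effects: Iterable[float]) -> tuple[Optional[float], int]:
    """Mean of the regulation signs over significant appearances.

    Returns ``(value, n)``; zero effects are excluded from both.  With no
    usable appearance the cell is undefined and ``(None, 0)`` is returned.
    """
    signs = [1.0 if e > 0 else -1.0 for e in effects if e != 0]
    if not signs:
        return None, 0
    return float(np.mean(signs)), len(signs)


@dataclass
class RegulationMatrix:
    """Genes x conditions matrix of mean regulation directions.

    ``values`` holds MeanRegDir in [-1, 1] (NaN = undefined cell); ``support``
    the per-cell count of contributing significant appearances.
    """

    values: pd.DataFrame
    support: pd.DataFrame

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.values.columns)

    def complete_rows(self, conditions: Optional[Sequence[str]] = None) -> pd.DataFrame:
        cols = list(conditions) if conditions is not None else self.conditions
        sub = self.values[cols]
        return sub[sub.notna().all(axis=1)]


def build_regulation_matrix(
    records: Iterable[DEGRecord],
    gene_subset: Iterable[str],
    conditions: Sequence[str],
    layer: str = "transcriptomic",
) -> RegulationMatrix:
    """Assemble the MeanRegDir matrix over ``gene_subset`` x ``conditions``.

    ``gene_subset`` is typically the all-conditions intersection of the
    layer, which guarantees a complete matrix.  Rows are sorted
    lexicographically by symbol so the output is independent of record order.
    """
    genes = sorted(set(gene_subset))
    effects: dict[tuple[str, str], list[float]] = {}
    gene_set = set(genes)
    for rec in records:
        if rec.layer == layer and rec.condition in conditions and rec.gene in gene_set:
            effects.setdefault((rec.gene, rec.condition), []).append(rec.effect)
    values = pd.DataFrame(np.nan, index=genes, columns=list(conditions), dtype=float)
    support = pd.DataFrame(0, index=genes, columns=list(conditions), dtype=int)
    missing = 0
    for gene in genes:
        for cond in conditions:
            v, n = mean_reg_dir(effects.get((gene, cond), []))
            support.loc[gene, cond] = n
            if v is None:
                missing += 1
            else:
                values.loc[gene, cond] = v
    if not genes:
        logger.warning("empty gene subset: regulation matrix has no rows")
    elif missing:
        logger.warning("%d regulation cells undefined (no significant appearance)", missing)
    return RegulationMatrix(values=values, support=support)


@dataclass(frozen=True)
class CorrelationResult:
    pair: tuple[str, str]
    r: Optional[float]
    p_value: Optional[float]
    m: int
    note: str = ""


@dataclass
class CorrelationTable:
    entries: list[CorrelationResult]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "condition_a": e.pair[0],
                    "condition_b": e.pair[1],
                    "r": e.r,
                    "p_value": e.p_value,
                    "m": e.m,
                    "note": e.note,
                }
                for e in self.entries
            ]
        )

    def get(self, a: str, b: str) -> CorrelationResult:
        want = frozenset((a, b))
        for e in self.entries:
            if frozenset(e.pair) == want:
                return e
        raise KeyError((a, b))


def correlation_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation with the two-sided t-distribution p-value.

    Identical to R's cor.test() default: t = r * sqrt((m-2)/(1-r^2)) on m-2
    degrees of freedom.  Requires m >= 3 and non-constant vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if len(x) < 3:
        raise ValueError(f"need at least 3 observations, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    res = pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def pairwise_condition_correlations(matrix: RegulationMatrix) -> CorrelationTable:
    """Pearson correlation for every unordered condition pair.

    Each pair uses the genes whose cells are defined in both conditions; a
    pair with fewer than 3 usable rows, or with a constant vector, is
    reported as not computable with the reason attached.
    """
    entries = []
    for a, b in combinations(matrix.conditions, 2):
        sub = matrix.complete_rows([a, b])
        m = len(sub)
        if m < 3:
            entries.append(CorrelationResult((a, b), None, None, m, "fewer than 3 usable rows"))
            continue
        try:
            r, p = correlation_test(sub[a].to_numpy(), sub[b].to_numpy())
        except ValueError as exc:
            entries.append(CorrelationResult((a, b), None, None, m, str(exc)))
            continue
        entries.append(CorrelationResult((a, b), r, p, m))
    return CorrelationTable(entries=entries)


@dataclass
class Dendrogram:
    """Agglomerative clustering of the condition columns.

    ``merges`` is the scipy linkage matrix (cluster ids, merge height,
    cluster size); leaf ids 0..m-1 index ``labels``.
    """

    labels: tuple[str, ...]
    merges: np.ndarray

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in leaves_list(self.merges)]

    def first_merge(self) -> tuple[str, ...]:
        """Labels of the leaves inside the first (lowest) merge."""
        a, b = int(self.merges[0, 0]), int(self.merges[0, 1])
        return tuple(sorted(self.labels[i] for i in (a, b) if i < len(self.labels)))

    def to_newick(self) -> str:
        m = len(self.labels)
        nodes: dict[int, str] = {i: self.labels[i] for i in range(m)}
        heights: dict[int, float] = {i: 0.0 for i in range(m)}
        for step, (a, b, h, _) in enumerate(self.merges):
            a, b, h = int(a), int(b), float(h)
            la = max(h - heights[a], 0.0)
            lb = max(h - heights[b], 0.0)
            nodes[m + step] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
            heights[m + step] = h
        return nodes[m + len(self.merges) - 1] + ";"


def cluster_conditions(
    matrix: RegulationMatrix, metric: str = "euclidean", method: str = "complete"
) -> Dendrogram:
    """Hierarchically cluster the condition columns of the regulation matrix.

    Euclidean distance with complete linkage by default.  Ties between equal
    merge distances are broken deterministically by the smaller cluster
    index (scipy's nearest-neighbor chain order on the given column order).
    Missing cells are an error: impute or subset first.
    """
    if len(matrix.conditions) < 2:
        raise ValueError("need at least 2 conditions to cluster")
    values = matrix.values
    if values.isna().any().any():
        raise ValueError(
            "regulation matrix has missing cells; restrict to the common "
            "gene set or impute before clustering"
        )
    Z = linkage(values.to_numpy().T, method=method, metric=metric)
    return Dendrogram(labels=tuple(matrix.conditions), merges=Z)
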