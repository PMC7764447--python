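"""Harmonization cascade for per-study differential-expression tables.

Fixed stage order per study and condition+layer group:

1. value conversions (fold change -> log2FC, -log10 p -> p),
2. row cleaning (missing gene names removed, multi-gene rows split),
3. within-study duplicate collapse (one gene, one vote per study),
4. FDR selection at alpha (default 0.05, boundary inclusive),
5. recurrence filter (a gene must be significant in >= 2 distinct studies of
   its condition+layer group),
6. restriction to the protein-coding universe.

The genomic layer carries membership-only reported-gene lists that are
pre-thresholded at the source; it bypasses stages 4 and 5 and only passes
through cleaning and the coding restriction.
"""

from __future__ import annotations

import logging
import math
import re
from collections import defaultdict
from dataclasses import replace
from typing import Iterable, Optional, Sequence

from .io_model import (
    DEGRecord,
    GeneSetCollection,
    QUANTITATIVE_LAYERS,
    StudyTable,
    normalize_symbol,
)

logger = logging.getLogger(__name__)

DEFAULT_FDR_ALPHA = 0.05
DEFAULT_MIN_STUDIES = 2

_MULTI_GENE_SPLIT = re.compile(r"[;,/|]|\s+")
_NA_TOKENS = {"", "NA", "N/A", "NAN", "NONE", "NULL", "-", "."}


def convert_effect(value: float, encoding: str) -> Optional[float]:
    """Convert an effect size to a signed log2 fold change.

    ``log2`` passes through.  ``ratio`` applies the signed-ratio convention
    common in curated supplementary tables: r > 0 -> log2(r), r < 0 ->
    -log2(|r|) (so -2 means a 0.5x change).  A ratio of 0 has no log and
    returns None (caller drops the record with a warning).
    """
    if encoding == "log2":
        return float(value)
    if encoding == "ratio":
        if value == 0:
            return None
        if value > 0:
            return math.log2(value)
        return -math.log2(-value)
    raise ValueError(f"unknown effect encoding {encoding!r}")


def convert_p(value: float, encoding: str) -> Optional[float]:
    """Convert a p-value to the raw [0, 1] scale.

    ``raw`` passes through (values outside [0, 1] return None and the record
    is dropped); ``neglog10`` maps v -> 10**(-v).
    """
    if encoding == "raw":
        if not 0.0 <= value <= 1.0:
            return None
        return float(value)
    if encoding == "neglog10":
        if value < 0:
            return None
        return 10.0 ** (-value)
    raise ValueError(f"unknown p encoding {encoding!r}")


def convert_table(
    table: StudyTable, effect_encoding: str = "log2", p_encoding: str = "raw"
) -> StudyTable:
    """Apply value conversions to every record; unconvertible records are
    dropped and counted."""
    out = StudyTable(
        study_id=table.study_id,
        condition=table.condition,
        layer=table.layer,
        provenance=table.provenance,
        n_dropped=table.n_dropped,
        warnings=list(table.warnings),
    )
    for rec in table.records:
        effect = rec.effect
        if effect is not None:
            effect = convert_effect(effect, effect_encoding)
            if effect is None:
                out.n_dropped += 1
                out.warnings.append(f"{rec.gene}: ratio effect of 0 dropped")
                continue
        p = rec.p
        if p is not None:
            p = convert_p(p, p_encoding)
            if p is None:
                out.n_dropped += 1
                out.warnings.append(f"{rec.gene}: unconvertible p-value dropped")
                continue
        fdr = rec.fdr
        if fdr is None and p is not None and rec.layer in QUANTITATIVE_LAYERS:
            # Some sources publish only an adjusted value labelled "p"; when no
            # separate FDR column is mapped the converted p is thresholded as-is.
            fdr = p
        if fdr is not None and not 0.0 <= fdr <= 1.0:
            out.n_dropped += 1
            out.warnings.append(f"{rec.gene}: FDR outside [0,1] dropped")
            continue
        out.records.append(replace(rec, effect=effect, p=p, fdr=fdr))
    return out


def _split_symbols(raw: str) -> list[str]:
    whole = normalize_symbol(raw)
    if whole in _NA_TOKENS:  # placeholder for a missing name, not a gene
        return []
    return [
        s
        for tok in _MULTI_GENE_SPLIT.split(raw)
        if (s := normalize_symbol(tok)) and s not in _NA_TOKENS
    ]


def clean_rows(table: StudyTable) -> StudyTable:
    """Remove rows with a missing gene name; split multi-gene rows.

    A row whose gene field holds several symbols (';', ',', '/', '|' or
    whitespace separated, as in proteomic tables mapping one protein to
    several genes) becomes one record per symbol, each copying the row's
    statistics.  Numeric fields are never altered.
    """
    out = StudyTable(
        study_id=table.study_id,
        condition=table.condition,
        layer=table.layer,
        provenance=table.provenance,
        n_dropped=table.n_dropped,
        warnings=list(table.warnings),
    )
    for rec in table.records:
        symbols = _split_symbols(rec.gene)
        if not symbols:
            out.n_dropped += 1
            continue
        for sym in symbols:
            out.records.append(replace(rec, gene=sym))
    return out


def _dedup_key(rec: DEGRecord):
    # smallest fdr wins; ties broken by largest |effect|, then first occurrence
    fdr = rec.fdr if rec.fdr is not None else float("inf")
    eff = abs(rec.effect) if rec.effect is not None else 0.0
    return (fdr, -eff)


def collapse_duplicates(table: StudyTable) -> StudyTable:
    """One gene, one vote per study: keep the best-supported record per gene.

    Multi-probe platforms report a gene several times within one study; the
    per-study appearance counting of the mean-direction statistic requires a
    single record.  Kept record: smallest FDR, ties by largest |effect|, then
    first occurrence.
    """
    best: dict[str, DEGRecord] = {}
    for rec in table.records:
        cur = best.get(rec.gene)
        if cur is None or _dedup_key(rec) < _dedup_key(cur):
            best[rec.gene] = rec
    # preserve first-occurrence order of the surviving records
    seen_order = []
    seen = set()
    for rec in table.records:
        if rec.gene not in seen:
            seen.add(rec.gene)
            seen_order.append(rec.gene)
    return StudyTable(
        study_id=table.study_id,
        condition=table.condition,
        layer=table.layer,
        records=[best[g] for g in seen_order],
        provenance=table.provenance,
        n_dropped=table.n_dropped,
        warnings=list(table.warnings),
    )


def filter_fdr(
    records: Iterable[DEGRecord], alpha: float = DEFAULT_FDR_ALPHA
) -> list[DEGRecord]:
    """Keep records with FDR <= alpha (boundary inclusive).

    Genomic-layer records are exempt (pre-thresholded reported-gene lists
    without an FDR column).  A quantitative-layer record without an FDR is a
    contract violation and raises.
    """
    kept = []
    for rec in records:
        if rec.layer not in QUANTITATIVE_LAYERS:
            kept.append(rec)
            continue
        if rec.fdr is None:
            raise ValueError(
                f"record {rec.gene} of study {rec.study_id} "
                f"({rec.layer}) has no FDR value"
            )
        if rec.fdr <= alpha:
            kept.append(rec)
    return kept


def recurrence_filter(
    records: Iterable[DEGRecord], min_studies: int = DEFAULT_MIN_STUDIES
) -> list[DEGRecord]:
    """Discard genes significant in fewer than ``min_studies`` distinct
    studies of their condition+layer group.

    Applies to transcriptomic and proteomic layers only; genomic records are
    study-level reported genes and exempt.  Surviving records keep their
    per-study values, which the mean-direction statistic needs.
    """
    records = list(records)
    studies: dict[tuple, set[str]] = defaultdict(set)
    for rec in records:
        if rec.layer in QUANTITATIVE_LAYERS:
            studies[(rec.condition, rec.layer, rec.gene)].add(rec.study_id)
    return [
        rec
        for rec in records
        if rec.layer not in QUANTITATIVE_LAYERS
        or len(studies[(rec.condition, rec.layer, rec.gene)]) >= min_studies
    ]


def restrict_to_coding(genes_or_records, universe) -> "set[str] | list[DEGRecord]":
    """Keep only items whose symbol is in the protein-coding universe.

    Accepts either a set of symbols or an iterable of records; the universe
    may be a :class:`GeneSetCollection` or any symbol collection.
    """
    if isinstance(universe, GeneSetCollection):
        if universe.universe is None:
            raise ValueError("collection has no universe")
        uni = universe.universe
    else:
        uni = frozenset(normalize_symbol(g) for g in universe)
    if not uni:
        raise ValueError("empty universe")
    if isinstance(genes_or_records, (set, frozenset)):
        return {g for g in genes_or_records if g in uni}
    return [rec for rec in genes_or_records if rec.gene in uni]


def harmonize_study(
    table: StudyTable, effect_encoding: str = "log2", p_encoding: str = "raw"
) -> StudyTable:
    """Per-study part of the cascade: convert, clean, collapse duplicates."""
    return collapse_duplicates(clean_rows(convert_table(table, effect_encoding, p_encoding)))


def harmonize_all(
    tables: Sequence[StudyTable],
    universe: Iterable[str] | GeneSetCollection,
    alpha: float = DEFAULT_FDR_ALPHA,
    min_studies: int = DEFAULT_MIN_STUDIES,
) -> tuple[dict[tuple[str, str], list[DEGRecord]], dict]:
    """Run the full cascade over already-converted study tables.

    Parameters
    ----------
    tables
        Study tables after :func:`harmonize_study` (or raw, if encodings are
        the defaults — conversion with default encodings is the identity on
        valid records).
    universe
        Protein-coding symbol universe.
    alpha, min_studies
        FDR threshold (inclusive) and the recurrence minimum.

    Returns
    -------
    groups, audit
        ``groups`` maps (condition, layer) to the surviving records;
        ``audit`` holds per-group record counts after each stage
        (non-increasing along the cascade).
    """
    pooled: dict[tuple[str, str], list[DEGRecord]] = defaultdict(list)
    for table in tables:
        pooled[(table.condition, table.layer)].extend(table.records)

    groups: dict[tuple[str, str], list[DEGRecord]] = {}
    audit: dict = {}
    for key in sorted(pooled):
        recs = pooled[key]
        counts = {"input": len(recs)}
        recs = filter_fdr(recs, alpha)
        counts["fdr"] = len(recs)
        recs = recurrence_filter(recs, min_studies)
        counts["recurrence"] = len(recs)
        recs = restrict_to_coding(recs, universe)
        counts["coding"] = len(recs)
        counts["genes"] = len({r.gene for r in recs})
        groups[key] = recs
        audit["%s/%s" % key] = counts
        logger.info("%s/%s: %s", key[0], key[1], counts)
    return groups, audit


def gene_sets_by_condition(
    groups: dict[tuple[str, str], list[DEGRecord]], layer: str
) -> dict[str, set[str]]:
    """Collapse harmonized record groups of one layer to per-condition gene sets."""
    return {
        cond: {r.gene for r in recs}
        for (cond, lay), recs in sorted(groups.items())
        if lay == layer and recs
    }
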