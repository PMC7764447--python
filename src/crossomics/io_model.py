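"""Domain types and file I/O for the cross-omics meta-analysis pipeline.

The pipeline consumes four kinds of plain-text inputs:

* per-study differential-expression tables (delimited text with a header),
* per-condition reported-gene lists for the genomic layer (one symbol per line),
* a protein-coding gene-symbol universe file (one symbol per line),
* gene-set collections in GMT format (GO / KEGG style).

All gene symbols are uppercased and stripped on ingest, since curated
supplementary tables mix case freely.  A YAML manifest ties study files to
their condition, omics layer, column mapping and value encodings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

LAYERS = ("genomic", "transcriptomic", "proteomic")
#: layers whose records carry per-gene effect sizes and FDR values
QUANTITATIVE_LAYERS = ("transcriptomic", "proteomic")


class ManifestError(ValueError):
    """Raised for an invalid or incomplete manifest entry."""


class FormatError(ValueError):
    """Raised for a malformed input file."""


def normalize_symbol(symbol: str) -> str:
    return symbol.strip().upper()


@dataclass(frozen=True)
class DEGRecord:
    """One gene's differential-expression result in one study.

    ``effect`` is the signed log2 fold change; its sign is the direction of
    regulation.  ``effect`` and ``fdr`` are required on the transcriptomic and
    proteomic layers and absent on the genomic layer, whose records are
    membership-only (reported-gene lists).
    """

    gene: str
    study_id: str
    condition: str
    layer: str
    effect: Optional[float] = None
    p: Optional[float] = None
    fdr: Optional[float] = None

    def validate(self) -> None:
        if not self.gene:
            raise ValueError("empty gene symbol")
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}")
        if self.layer in QUANTITATIVE_LAYERS:
            if self.effect is None:
                raise ValueError(
                    f"{self.layer} record for {self.gene} lacks an effect size"
                )
            if self.fdr is None:
                raise ValueError(f"{self.layer} record for {self.gene} lacks an FDR")
        if self.fdr is not None and not 0.0 <= self.fdr <= 1.0:
            raise ValueError(f"FDR {self.fdr} outside [0, 1] for {self.gene}")


@dataclass
class StudyTable:
    """All records of one study on one condition and omics layer."""

    study_id: str
    condition: str
    layer: str
    records: list[DEGRecord] = field(default_factory=list)
    provenance: str = ""
    n_dropped: int = 0
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for rec in self.records:
            if (rec.study_id, rec.condition, rec.layer) != (
                self.study_id,
                self.condition,
                self.layer,
            ):
                raise ValueError(
                    f"record {rec.gene} does not belong to study "
                    f"{self.study_id}/{self.condition}/{self.layer}"
                )

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: frozenset[str]


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT) plus the population universe.

    The universe doubles as the protein-coding filter and as the population
    ``N`` of every hypergeometric test.
    """

    sets: dict[str, GeneSet] = field(default_factory=dict)
    universe: Optional[frozenset[str]] = None

    @property
    def universe_size(self) -> int:
        if self.universe is None:
            raise ValueError("collection has no universe")
        return len(self.universe)

    def restricted(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Return a copy with members intersected with ``universe``."""
        uni = frozenset(normalize_symbol(g) for g in universe)
        sets = {
            name: GeneSet(s.name, s.description, s.members & uni)
            for name, s in self.sets.items()
        }
        return GeneSetCollection(sets=sets, universe=uni)


@dataclass
class ManifestEntry:
    path: Path
    study_id: str
    condition: str
    layer: str
    columns: dict[str, str]
    encodings: dict[str, str] = field(default_factory=dict)
    delimiter: str = "\t"
    provenance: str = ""

    @property
    def effect_encoding(self) -> str:
        return self.encodings.get("effect", "log2")

    @property
    def p_encoding(self) -> str:
        return self.encodings.get("p", "raw")


@dataclass
class Manifest:
    entries: list[ManifestEntry]
    population_path: Optional[Path] = None
    gmt_paths: list[Path] = field(default_factory=list)
    root: Path = Path(".")


def _require(mapping: Mapping, key: str, context: str):
    if key not in mapping:
        raise ManifestError(f"{context}: missing required key {key!r}")
    return mapping[key]


def read_manifest(path: str | Path) -> Manifest:
    """Read and validate a YAML manifest.

    Relative file paths are resolved against the manifest's directory.  Every
    entry must name an existing file, a known layer, and a gene column;
    transcriptomic/proteomic entries must additionally map an effect column
    and a p or fdr column.
    """
    path = Path(path)
    if not path.exists():
        raise ManifestError(f"manifest not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "entries" not in raw:
        raise ManifestError(f"{path}: manifest must be a mapping with 'entries'")
    root = path.parent
    entries: list[ManifestEntry] = []
    for i, ent in enumerate(raw["entries"]):
        ctx = f"{path} entry {i} ({ent.get('study_id', '?')})"
        layer = _require(ent, "layer", ctx)
        if layer not in LAYERS:
            raise ManifestError(f"{ctx}: unknown layer {layer!r} (one of {LAYERS})")
        columns = dict(_require(ent, "columns", ctx))
        if "gene" not in columns:
            raise ManifestError(f"{ctx}: column mapping must name a gene column")
        if layer in QUANTITATIVE_LAYERS:
            if "effect" not in columns:
                raise ManifestError(f"{ctx}: {layer} entry needs an effect column")
            if "p" not in columns and "fdr" not in columns:
                raise ManifestError(f"{ctx}: {layer} entry needs a p or fdr column")
        fpath = root / _require(ent, "path", ctx)
        if not fpath.exists():
            raise ManifestError(f"{ctx}: file not found: {fpath}")
        entries.append(
            ManifestEntry(
                path=fpath,
                study_id=str(_require(ent, "study_id", ctx)),
                condition=str(_require(ent, "condition", ctx)),
                layer=layer,
                columns=columns,
                encodings=dict(ent.get("encodings", {})),
                delimiter=ent.get("delimiter", "\t"),
                provenance=str(ent.get("provenance", "")),
            )
        )
    population_path = None
    if raw.get("population"):
        population_path = root / raw["population"]
        if not population_path.exists():
            raise ManifestError(f"population file not found: {population_path}")
    gmt_paths = []
    for g in raw.get("gmt", []) or []:
        gpath = root / g
        if not gpath.exists():
            raise ManifestError(f"GMT file not found: {gpath}")
        gmt_paths.append(gpath)
    return Manifest(
        entries=entries, population_path=population_path, gmt_paths=gmt_paths, root=root
    )


def _opt_float(value) -> Optional[float]:
    return None if pd.isna(value) else float(value)


def read_study_table(entry: ManifestEntry) -> StudyTable:
    """Read one delimited study file into raw (pre-harmonization) records.

    Rows whose mapped numeric columns do not parse are dropped and counted in
    ``n_dropped``; a header-only file yields an empty table with a warning
    rather than an error.  Gene symbols are uppercased; value encodings are
    left untouched here and resolved by the harmonization cascade.
    """
    df = pd.read_csv(entry.path, sep=entry.delimiter, dtype=str)
    table = StudyTable(
        study_id=entry.study_id,
        condition=entry.condition,
        layer=entry.layer,
        provenance=entry.provenance or str(entry.path),
    )
    missing = [c for c in entry.columns.values() if c not in df.columns]
    if missing:
        raise FormatError(f"{entry.path}: mapped columns absent from header: {missing}")
    if df.empty:
        table.warnings.append(f"{entry.path}: no data rows")
        logger.warning("%s: no data rows", entry.path)
        return table

    genes = df[entry.columns["gene"]].astype(str)
    numeric = {}
    for key in ("effect", "p", "fdr"):
        col = entry.columns.get(key)
        if col is not None:
            numeric[key] = pd.to_numeric(df[col], errors="coerce")

    quantitative = entry.layer in QUANTITATIVE_LAYERS
    for i in range(len(df)):
        vals = {k: _opt_float(v.iloc[i]) for k, v in numeric.items()}
        if quantitative:
            required = ["effect"] + (["fdr"] if "fdr" in numeric else ["p"])
            if any(vals.get(k) is None for k in required):
                table.n_dropped += 1
                continue
        table.records.append(
            DEGRecord(
                gene=normalize_symbol(genes.iloc[i]),
                study_id=entry.study_id,
                condition=entry.condition,
                layer=entry.layer,
                effect=vals.get("effect"),
                p=vals.get("p"),
                fdr=vals.get("fdr"),
            )
        )
    if table.n_dropped:
        logger.info("%s: dropped %d unparseable rows", entry.path, table.n_dropped)
    return table


def read_entry(entry: ManifestEntry) -> StudyTable:
    """Read any manifest entry into a StudyTable.

    Quantitative layers are delimited tables (:func:`read_study_table`);
    genomic entries are plain reported-gene lists, turned into
    membership-only records.
    """
    if entry.layer != "genomic":
        return read_study_table(entry)
    symbols = read_gene_list(entry.path)
    return StudyTable(
        study_id=entry.study_id,
        condition=entry.condition,
        layer="genomic",
        records=[
            DEGRecord(
                gene=g,
                study_id=entry.study_id,
                condition=entry.condition,
                layer="genomic",
            )
            for g in sorted(symbols)
        ],
        provenance=entry.provenance or str(entry.path),
    )


def write_study_table(table: StudyTable, path: str | Path) -> None:
    """Write records as a TSV readable by :func:`read_study_table`."""
    rows = [
        {
            "gene": r.gene,
            "effect": "" if r.effect is None else repr(r.effect),
            "p": "" if r.p is None else repr(r.p),
            "fdr": "" if r.fdr is None else repr(r.fdr),
        }
        for r in table.records
    ]
    pd.DataFrame(rows, columns=["gene", "effect", "p", "fdr"]).to_csv(
        path, sep="\t", index=False
    )


def read_gene_list(path: str | Path) -> set[str]:
    """Read a one-symbol-per-line list; '#' lines are comments.

    Symbols are uppercased and deduplicated.  An empty result is an error: a
    population of size 0 is never a valid universe.
    """
    symbols: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            symbols.add(normalize_symbol(line))
    if not symbols:
        raise FormatError(f"{path}: gene list is empty")
    return symbols


def write_gene_list(symbols: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sorted(symbols):
            fh.write(s + "\n")


def read_gmt(path: str | Path, universe: Optional[Iterable[str]] = None) -> GeneSetCollection:
    """Read a GMT file: ``name <TAB> description <TAB> member...`` per line.

    Member symbols are uppercased.  A line with fewer than two fields is a
    format error; a set with no members is skipped with a warning; on a
    duplicate set name the later entry wins (warning logged).
    """
    sets: dict[str, GeneSet] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs at least name and description"
                )
            name, description, *members = fields
            members = [normalize_symbol(m) for m in members if m.strip()]
            if not members:
                logger.warning("%s:%d: set %r has no members; skipped", path, lineno, name)
                continue
            if name in sets:
                logger.warning("%s:%d: duplicate set name %r; later entry wins", path, lineno, name)
            sets[name] = GeneSet(name=name, description=description, members=frozenset(members))
    uni = frozenset(normalize_symbol(g) for g in universe) if universe is not None else None
    return GeneSetCollection(sets=sets, universe=uni)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            s = collection.sets[name]
            fh.write("\t".join([s.name, s.description, *sorted(s.members)]) + "\n")
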