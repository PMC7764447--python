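"""Synthetic study bundles with planted ground truth.

The generator emulates the post-differential-expression summary tables the
pipeline consumes — never raw expression, probes or genotypes.  A bundle
consists of a synthetic protein-coding universe, per-study TSV tables for
the transcriptomic and proteomic layers, per-condition reported-gene lists
for the genomic layer, a GMT collection with planted enriched terms plus
decoys, a ready-to-run manifest, and a truth JSON for assertions.

Planted structure
-----------------
Genes are allocated into disjoint groups: a shared set present in all
conditions (default 139, the size of a typical all-conditions
transcriptomic intersection), extra per-pair overlaps, per-condition
private genes, and singleton genes significant in exactly one study
(recurrence-filter fodder).

Direction concordance between conditions is planted through a latent sign
z per shared gene: condition c observes z with its agreement probability
a_c, else -z.  Two conditions then agree on a shared gene with probability
a_c*a_d + (1-a_c)*(1-a_d), and the expected Pearson correlation of their
±1 direction vectors is 2*concordance - 1.  A uniform pairwise concordance
c >= 1/2 corresponds to a_c = (1 + sqrt(2c-1))/2 for every condition.
Agreement is realized with exact per-condition counts (a derandomized
binomial), so with two conditions the planted pairwise concordance is exact
up to rounding.

Each study observes a planted gene's base direction flipped independently
with probability ``flip_noise``; effect magnitudes are 0.3 + Exp(mean 0.8)
(strictly positive, sign carried separately — magnitude never enters the
mean-direction statistic), significant FDR values are Uniform(0, alpha]
and background FDR values Uniform(alpha, 1].

Determinism: one global seed; every output file draws from a substream
derived by hashing its (condition, layer, study) identity, so adding a
study never perturbs existing files, and identical configs produce
byte-identical bundles.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

DEFAULT_CONDITIONS = ("AD", "PD", "HD", "ALS")


@dataclass(frozen=True)
class PlantedTerm:
    """One gene set planted into the GMT collection.

    ``strength`` is the fraction of members drawn from the designated gene
    group (``shared``, ``private:<condition>`` or ``pair:<a>|<b>``); the
    rest are decoy members sampled from the remaining universe.
    """

    name: str
    group: str = "shared"
    strength: float = 1.0
    size: int = 100


@dataclass
class SimulationConfig:
    seed: int = 0
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    transcriptomic_studies: int = 10
    proteomic_studies: int = 3
    universe_size: int = 19324
    n_shared: int = 139
    n_pairwise: int = 25
    n_private: int = 300
    n_singletons: int = 50
    n_background: int = 200
    #: uniform pairwise concordance in [0,1] (values < 0.5 need exactly two
    #: conditions), or a mapping condition -> agreement probability a_c
    concordance: "float | dict[str, float]" = 0.75
    flip_noise: float = 0.0
    effect_floor: float = 0.3
    effect_scale: float = 0.8
    fdr_alpha: float = 0.05
    proteomic_fraction: float = 0.3
    genomic_fraction: float = 0.2
    n_decoy_terms: int = 100
    decoy_size_range: tuple[int, int] = (20, 200)
    planted_terms: tuple[PlantedTerm, ...] = (PlantedTerm("PLANTED_SHARED"),)

    def validate(self) -> None:
        pairs = len(self.conditions) * (len(self.conditions) - 1) // 2
        planted = (
            self.n_shared
            + pairs * self.n_pairwise
            + len(self.conditions) * self.n_private
            + self.n_singletons
        )
        if planted > self.universe_size:
            raise ValueError(
                f"infeasible allocation: {planted} planted genes exceed the "
                f"universe of {self.universe_size}"
            )
        if not 0.0 <= self.flip_noise <= 1.0:
            raise ValueError("flip_noise must lie in [0, 1]")
        if isinstance(self.concordance, (int, float)):
            if not 0.0 <= self.concordance <= 1.0:
                raise ValueError("concordance must lie in [0, 1]")
            if self.concordance < 0.5 and len(self.conditions) != 2:
                raise ValueError(
                    "a uniform pairwise concordance below 0.5 is only "
                    "realizable for exactly two conditions"
                )


@dataclass
class Truth:
    """Serializable planted ground truth of one bundle."""

    conditions: tuple[str, ...]
    shared: list[str]
    pairwise: dict[str, list[str]]
    private: dict[str, list[str]]
    singletons: list[dict]
    base_dir: dict[str, dict[str, int]]
    agreement: dict[str, float]

    def condition_genes(self, condition: str) -> set[str]:
        """All planted (non-singleton) genes of one condition."""
        genes = set(self.shared) | set(self.private[condition])
        for pair_key, members in self.pairwise.items():
            if condition in pair_key.split("|"):
                genes |= set(members)
        return genes

    def group(self, name: str) -> list[str]:
        if name == "shared":
            return list(self.shared)
        kind, _, rest = name.partition(":")
        if kind == "private":
            return list(self.private[rest])
        if kind == "pair":
            return list(self.pairwise[rest])
        raise KeyError(name)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=1, default=list)

    @classmethod
    def from_json(cls, text: str) -> "Truth":
        raw = json.loads(text)
        raw["conditions"] = tuple(raw["conditions"])
        return cls(**raw)


def agreement_for_concordance(c: float) -> float:
    """Per-condition agreement probability giving uniform pairwise
    concordance c = a^2 + (1-a)^2; requires c >= 1/2."""
    if not 0.5 <= c <= 1.0:
        raise ValueError("uniform concordance must lie in [0.5, 1]")
    return (1.0 + math.sqrt(2.0 * c - 1.0)) / 2.0


def _substream(seed: int, *tokens) -> np.random.Generator:
    crc = zlib.crc32("/".join(map(str, tokens)).encode())
    return np.random.default_rng(np.random.SeedSequence([seed % (2**31), crc]))


def generate_universe(config: SimulationConfig) -> list[str]:
    """Synthetic symbol universe G000001..; deterministic by construction."""
    if config.universe_size < 1:
        raise ValueError("universe_size must be positive")
    return [f"G{i + 1:06d}" for i in range(config.universe_size)]


def _agreements(config: SimulationConfig) -> dict[str, float]:
    if isinstance(config.concordance, dict):
        missing = set(config.conditions) - set(config.concordance)
        if missing:
            raise ValueError(f"concordance mapping lacks conditions {sorted(missing)}")
        return {c: float(config.concordance[c]) for c in config.conditions}
    c = float(config.concordance)
    if c >= 0.5:
        a = agreement_for_concordance(c)
        return {cond: a for cond in config.conditions}
    # two conditions: reference scheme realizes any concordance exactly
    first, second = config.conditions
    return {first: 1.0, second: c}


def generate_condition_truth(
    config: SimulationConfig, universe: Optional[Sequence[str]] = None
) -> Truth:
    """Allocate planted gene groups and per-condition base directions."""
    config.validate()
    if universe is None:
        universe = generate_universe(config)
    cursor = 0

    def take(n: int) -> list[str]:
        nonlocal cursor
        chunk = list(universe[cursor : cursor + n])
        cursor += n
        return chunk

    shared = take(config.n_shared)
    pairwise = {
        "|".join(pair): take(config.n_pairwise)
        for pair in combinations(config.conditions, 2)
    }
    private = {cond: take(config.n_private) for cond in config.conditions}

    rng = _substream(config.seed, "truth")
    agreement = _agreements(config)
    base_dir: dict[str, dict[str, int]] = {c: {} for c in config.conditions}
    # Latent sign z per shared gene; each condition keeps z on an exact count
    # round(a_c * n_shared) of genes (derandomized binomial), so the realized
    # agreement fraction equals a_c up to rounding and, with two conditions,
    # the pairwise concordance is exact.
    latent = {gene: (1 if rng.random() < 0.5 else -1) for gene in shared}
    for cond in config.conditions:
        n_keep = round(agreement[cond] * len(shared))
        keep = set(rng.permutation(len(shared))[:n_keep]) if shared else set()
        for i, gene in enumerate(shared):
            z = latent[gene]
            base_dir[cond][gene] = z if i in keep else -z
    for pair_key, members in pairwise.items():
        for gene in members:
            for cond in pair_key.split("|"):
                base_dir[cond][gene] = 1 if rng.random() < 0.5 else -1
    for cond, members in private.items():
        for gene in members:
            base_dir[cond][gene] = 1 if rng.random() < 0.5 else -1

    singleton_genes = take(config.n_singletons)
    singletons = []
    for gene in singleton_genes:
        cond = config.conditions[int(rng.integers(len(config.conditions)))]
        study = int(rng.integers(config.transcriptomic_studies))
        direction = 1 if rng.random() < 0.5 else -1
        singletons.append(
            {
                "gene": gene,
                "condition": cond,
                "study_id": f"{cond}_tx_{study + 1:02d}",
                "direction": direction,
            }
        )
    return Truth(
        conditions=config.conditions,
        shared=shared,
        pairwise=pairwise,
        private=private,
        singletons=singletons,
        base_dir=base_dir,
        agreement=agreement,
    )


def _draw_effect(rng: np.random.Generator, sign: int, config: SimulationConfig) -> float:
    return sign * (config.effect_floor + rng.exponential(config.effect_scale))


def _significant_fdr(rng: np.random.Generator, alpha: float) -> float:
    return alpha * (1.0 - rng.random())  # Uniform(0, alpha]


def _background_fdr(rng: np.random.Generator, alpha: float) -> float:
    return alpha + (1.0 - alpha) * (1.0 - rng.random())  # Uniform(alpha, 1]


def _write_study_tsv(
    path: Path,
    rows: list[tuple[str, float, float, float]],
) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tlog2fc\tp\tfdr\n")
        for gene, eff, p, fdr in rows:
            fh.write(f"{gene}\t{eff:.6f}\t{p:.6g}\t{fdr:.6g}\n")


def _study_rows(
    rng: np.random.Generator,
    genes: Sequence[str],
    base_dir: dict[str, int],
    config: SimulationConfig,
    background_pool: Sequence[str],
) -> list[tuple[str, float, float, float]]:
    rows = []
    for gene in genes:
        sign = base_dir[gene]
        if config.flip_noise and rng.random() < config.flip_noise:
            sign = -sign
        fdr = _significant_fdr(rng, config.fdr_alpha)
        rows.append((gene, _draw_effect(rng, sign, config), fdr * rng.random(), fdr))
    if config.n_background and len(background_pool):
        picks = rng.choice(len(background_pool), size=min(config.n_background, len(background_pool)), replace=False)
        for i in sorted(picks):
            gene = background_pool[i]
            sign = 1 if rng.random() < 0.5 else -1
            fdr = _background_fdr(rng, config.fdr_alpha)
            rows.append((gene, _draw_effect(rng, sign, config), fdr * rng.random(), fdr))
    return rows


def _head_fraction(genes: Sequence[str], fraction: float) -> list[str]:
    return list(genes[: math.ceil(fraction * len(genes))])


def _group_fraction(truth: Truth, condition: str, fraction: float) -> list[str]:
    """A deterministic per-group subset of one condition's planted genes.

    Taking the head fraction of every group separately (shared, each pair
    involving the condition, private) scales the planted overlap structure
    down instead of collapsing it onto the shared set.
    """
    genes = _head_fraction(truth.shared, fraction)
    for pair_key, members in truth.pairwise.items():
        if condition in pair_key.split("|"):
            genes += _head_fraction(members, fraction)
    genes += _head_fraction(truth.private[condition], fraction)
    return sorted(genes)


def generate_study_tables(
    config: SimulationConfig, truth: Truth, outdir: Path
) -> list[dict]:
    """Write per-study TSVs and genomic gene lists; return manifest entries.

    Transcriptomic studies carry every planted gene of their condition (plus
    that study's singletons and non-significant background rows); proteomic
    studies carry a deterministic subset of the planted genes, mirroring the
    sparser proteomic coverage; the genomic layer emits symbol lists only.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    universe = generate_universe(config)
    planted_all = set(truth.shared) | {s["gene"] for s in truth.singletons}
    for members in truth.pairwise.values():
        planted_all |= set(members)
    for members in truth.private.values():
        planted_all |= set(members)
    background_pool = [g for g in universe if g not in planted_all]

    entries: list[dict] = []
    for cond in config.conditions:
        cond_genes = sorted(truth.condition_genes(cond))
        singles_by_study: dict[str, list[dict]] = {}
        for s in truth.singletons:
            if s["condition"] == cond:
                singles_by_study.setdefault(s["study_id"], []).append(s)

        for i in range(config.transcriptomic_studies):
            study_id = f"{cond}_tx_{i + 1:02d}"
            rng = _substream(config.seed, cond, "transcriptomic", i)
            base = dict(truth.base_dir[cond])
            genes = list(cond_genes)
            for s in singles_by_study.get(study_id, []):
                genes.append(s["gene"])
                base[s["gene"]] = s["direction"]
            rows = _study_rows(rng, genes, base, config, background_pool)
            fname = f"{study_id}.tsv"
            _write_study_tsv(outdir / fname, rows)
            entries.append(
                {
                    "path": fname,
                    "study_id": study_id,
                    "condition": cond,
                    "layer": "transcriptomic",
                    "columns": {"gene": "gene", "effect": "log2fc", "p": "p", "fdr": "fdr"},
                    "encodings": {"effect": "log2", "p": "raw"},
                }
            )

        proteomic_genes = _group_fraction(truth, cond, config.proteomic_fraction)
        for i in range(config.proteomic_studies):
            study_id = f"{cond}_pr_{i + 1:02d}"
            rng = _substream(config.seed, cond, "proteomic", i)
            rows = _study_rows(rng, proteomic_genes, truth.base_dir[cond], config, background_pool)
            fname = f"{study_id}.tsv"
            _write_study_tsv(outdir / fname, rows)
            entries.append(
                {
                    "path": fname,
                    "study_id": study_id,
                    "condition": cond,
                    "layer": "proteomic",
                    "columns": {"gene": "gene", "effect": "log2fc", "p": "p", "fdr": "fdr"},
                    "encodings": {"effect": "log2", "p": "raw"},
                }
            )

        genomic_genes = _group_fraction(truth, cond, config.genomic_fraction)
        fname = f"{cond}_genomic.txt"
        with open(outdir / fname, "w") as fh:
            fh.write(f"# reported genes, condition {cond}\n")
            for g in genomic_genes:
                fh.write(g + "\n")
        entries.append(
            {
                "path": fname,
                "study_id": f"{cond}_gwas",
                "condition": cond,
                "layer": "genomic",
                "columns": {"gene": "gene"},
            }
        )
    return entries


def generate_gmt(config: SimulationConfig, truth: Truth, path: Path) -> None:
    """Write planted terms plus uniform decoy terms as a GMT file."""
    universe = generate_universe(config)
    rng = _substream(config.seed, "gmt")
    lines = []
    for term in config.planted_terms:
        group = truth.group(term.group)
        # strength = fraction of members from the group; a group smaller than
        # strength*size shrinks the term rather than diluting it with decoys
        n_from_group = min(round(term.strength * term.size), len(group))
        members = list(rng.choice(group, size=n_from_group, replace=False))
        n_rest = term.size - round(term.strength * term.size)
        if n_rest > 0:
            pool = [g for g in universe if g not in set(group)]
            members += list(rng.choice(pool, size=n_rest, replace=False))
        lines.append((term.name, f"planted:{term.group}:{term.strength}", sorted(members)))
    lo, hi = config.decoy_size_range
    for d in range(config.n_decoy_terms):
        size = int(rng.integers(lo, hi + 1))
        members = sorted(rng.choice(universe, size=size, replace=False))
        lines.append((f"DECOY_{d + 1:03d}", "decoy", members))
    with open(path, "w") as fh:
        for name, desc, members in lines:
            fh.write("\t".join([name, desc, *members]) + "\n")


@dataclass
class SimulationBundle:
    """Paths of one generated bundle."""

    outdir: Path
    manifest_path: Path
    population_path: Path
    gmt_path: Path
    truth_path: Path
    truth: Truth
    config: SimulationConfig


def simulate(config: SimulationConfig, outdir: "str | Path") -> SimulationBundle:
    """Generate a complete bundle: universe, studies, GMT, manifest, truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    universe = generate_universe(config)
    population_path = outdir / "population.txt"
    with open(population_path, "w") as fh:
        fh.write("# synthetic protein-coding universe\n")
        for g in universe:
            fh.write(g + "\n")

    truth = generate_condition_truth(config, universe)
    truth_path = outdir / "truth.json"
    truth_path.write_text(truth.to_json())

    entries = generate_study_tables(config, truth, outdir)
    gmt_path = outdir / "genesets.gmt"
    generate_gmt(config, truth, gmt_path)

    manifest = {
        "entries": entries,
        "population": "population.txt",
        "gmt": ["genesets.gmt"],
    }
    manifest_path = outdir / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return SimulationBundle(
        outdir=outdir,
        manifest_path=manifest_path,
        population_path=population_path,
        gmt_path=gmt_path,
        truth_path=truth_path,
        truth=truth,
        config=config,
    )
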