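# Methods

## Scope and data model

`crossomics` operates exclusively on *post-differential-expression summary
tables*: one row per gene per study with a signed log2 fold change and an
FDR-adjusted significance value. It never touches raw expression matrices,
probes, spectra or genotypes. Three omics layers are distinguished:

- **transcriptomic / proteomic** — quantitative layers; records carry an
  effect size and an FDR and pass the full filtering cascade;
- **genomic** — membership-only reported-gene lists (GWAS-catalog style),
  already thresholded at the source (typically SNP-trait p < 1e-5); these
  bypass the FDR and recurrence filters and only pass the protein-coding
  restriction.

A YAML manifest binds each study file to its condition, layer, column
mapping and value encodings, so heterogeneous supplementary-table dialects
can be ingested without editing the files.

## Harmonization cascade

Fixed order: convert → clean → collapse duplicates → FDR filter →
recurrence filter → coding restriction. Rationale and edge rules:

- **Conversions.** `ratio` effect sizes use the signed-ratio convention
  (−2 means 0.5×), common in curated supplementary tables; a ratio of 0
  has no logarithm and drops the record with a warning. `neglog10`
  p-values map v → 10^(−v). When a source provides only an adjusted value
  in its p column, that value is thresholded as the FDR.
- **Cleaning.** Rows with missing gene names (including placeholder
  tokens NA, N/A, "-", ".") are removed; rows whose gene field holds
  several symbols (';', ',', '/', '|', whitespace — typical of proteomic
  protein-to-gene mappings) become one record per symbol, copying the
  row's statistics unchanged.
- **Duplicate collapse.** Multi-probe platforms report one gene several
  times per study. Since the mean-direction statistic counts per-study
  appearances, each study must contribute one vote per gene: the record
  with the smallest FDR is kept (ties: largest |effect|, then first
  occurrence). The source literature is silent on this point; this is a
  package design decision.
- **FDR filter.** FDR ≤ α with α = 0.05, boundary inclusive.
- **Recurrence filter.** A gene survives in a condition+layer group only
  if it is significant in ≥ 2 *distinct study ids* of that group; this
  removes genes that appear once by chance. "Experiment" is equated with
  a manifest entry's `study_id`: several contrasts inside one source
  study must be registered as separate entries to count separately. The
  surviving records keep their per-study values (the mean-direction
  statistic needs them).
- **Coding restriction.** Symbols outside the supplied protein-coding
  universe are removed. The universe also fixes the population size N of
  every hypergeometric test; 19,324 (an HGNC protein-coding snapshot
  size) is the default when no universe file is given, and the supplied
  file's cardinality overrides it. Because the coding restriction and the
  recurrence filter test disjoint record attributes, their order is
  immaterial (property-tested).

No gene-symbol alias resolution is attempted beyond uppercasing; wiring in
an alias table is out of scope.

## Overlap statistics

Two complementary views: the *exclusive Venn partition* (each gene in the
region of exactly the conditions containing it; all 2^m − 1 regions
materialized) and *full pairwise intersections* k = |A ∩ B|, tested with
the one-sided upper-tail hypergeometric probability P(X ≥ k) including the
observed k. scipy evaluates the tail through log-gamma, which is stable at
N ≈ 2×10⁴; overlaps so extreme that the tail underflows double precision
are clamped to the smallest positive float (5e−324) so p stays in (0, 1].
The six pairwise tests per layer are reported at their raw hypergeometric
significance; a BH-adjusted column is attached for convenience but is
explicitly secondary.

## Regulation concordance

MeanRegDir(gene) = (1/n) Σ sig(effectᵢ) over the gene's significant
appearances in one condition and layer, pooled across all that condition's
studies. sig is undefined at 0, so records with an effect of exactly 0 are
excluded from both the numerator and n (such records cannot arise from a
significant differential-expression call in practice; the rule keeps the
invariant |MeanRegDir| = 1 ⇔ all signs agree). Cells with no usable
appearance are reported as missing.

Condition pairs are compared by Pearson correlation over the genes defined
in both conditions, with the two-sided t-distribution p-value
(t = r√((m−2)/(1−r²)), m−2 df) — the default behavior of R's `cor.test()`.
Pairs with fewer than 3 usable genes or a constant vector are reported as
not computable, with the reason, rather than raising.

Conditions are clustered on the gene × condition matrix with Euclidean
distance and complete linkage — the defaults of the common
heatmap-with-dendrogram workflow — both configurable. Equal-distance merges
resolve deterministically via scipy's nearest-neighbor-chain order on the
given column order (lower leaf index first). The dendrogram is exported as
Newick; no heatmap image is rendered.

## Over-representation analysis and term reduction

ORA tests a query list against every set of a GMT collection with the same
hypergeometric tail, the universe being the protein-coding population
("reference = genome" convention); a `background=` argument allows the
stricter measured-gene background instead. BH adjustment (the field's
default FDR procedure; delegated to statsmodels and property-tested
against a hand step-up oracle) runs across all sets of one collection;
significance means BH-FDR ≤ 0.05. The enrichment ratio is (k/n)/(K/N).

Because GO-style collections yield many overlapping significant terms, the
significant set can be reduced to exemplars by affinity propagation over a
term–term similarity matrix: Jaccard index of member genes restricted to
the universe (overlap coefficient available as an option), preference =
median off-diagonal similarity, damping 0.9, ≤ 1000 iterations, 100-
iteration convergence window — the defaults of the standard affinity-
propagation clustering package. The responsibility/availability updates
are implemented directly:

    r(i,k) ← s(i,k) − max_{k′≠k}[a(i,k′) + s(i,k′)]
    a(i,k) ← min(0, r(k,k) + Σ_{i′∉{i,k}} max(0, r(i′,k)))   (i ≠ k)
    a(k,k) ← Σ_{i′≠k} max(0, r(i′,k))

Unlike implementations that inject tiny random noise into S to break
degeneracies, this one is strictly deterministic: exactly symmetric inputs
(duplicated or mutually disjoint terms) drive every candidate's evidence
r(k,k)+a(k,k) to 0, and that tie is resolved by an exhaustive
net-similarity search over exemplar subsets (≤ 15 points; greedy beyond),
preferring more exemplars and then lower indices among equal-net subsets —
so an unrepresented point remains its own exemplar, and ties go to the
alphabetically/index-first term. Exact-duplicate member sets are collapsed
before clustering and inherit their representative's exemplar. Evidence
within numerical round-off of 0 is treated as a tie, not a choice.

GO DAG topology and KEGG pathway graphs are not modelled; gene sets are
flat GMT.

## Synthetic worlds

The generator emits the complete input surface (universe file, per-study
TSVs, genomic lists, GMT, manifest, truth JSON) from a single config:

- **Gene groups.** A shared set planted in all conditions (default 139 —
  the size of a representative all-conditions transcriptomic
  intersection), per-pair extras (default 25), per-condition private
  genes (default 300, giving ≈ 514 planted DEGs per condition), and
  singleton genes appearing in exactly one study (default 50) as
  recurrence-filter fodder. Groups are disjoint by construction.
- **Directions.** Each shared gene gets a latent sign z; condition c
  observes z with agreement probability a_c, realized with *exact* counts
  (a derandomized binomial), so pairwise concordance
  a_c·a_d + (1−a_c)(1−a_d) concentrates at its target and is exact for
  two conditions. A uniform concordance c ≥ ½ maps to
  a = (1 + √(2c−1))/2; c < ½ is only jointly realizable for two
  conditions (reference scheme) and rejected otherwise. The expected
  Pearson correlation between two conditions' ±1 direction vectors is
  2c − 1.
- **Observations.** Each study flips a planted gene's sign independently
  with probability ε (default 0 — the noise-free reference world);
  |effect| ~ 0.3 + Exp(mean 0.8) (strictly positive, unbounded; the
  magnitude never enters the statistic, only the sign does); significant
  FDRs ~ Uniform(0, α], background FDRs ~ Uniform(α, 1] — the pipeline
  only thresholds FDR, it never models it. Default 10 transcriptomic and
  3 proteomic studies per condition; the proteomic layer reuses a
  deterministic 30% head-subset of each condition's planted genes
  (sparser coverage, overlap structure preserved), the genomic layer
  emits a 20% subset as symbol lists.
- **Gene sets.** One planted term of strength 1.0 over the shared set
  (strength = fraction of members from the group; smaller groups shrink
  the term rather than diluting it) plus 100 uniform decoy terms of size
  20–200.
- **Determinism.** One global seed; every output file draws from a
  substream keyed by CRC32 of (condition, layer, study index), so adding
  a study never perturbs existing files and identical configs are
  byte-identical.

What a green synthetic test does *not* establish: the generator draws
effect magnitudes i.i.d., plants FDR values directly rather than deriving
them from test statistics, uses synthetic symbols with no aliasing
problems, and gives every study full coverage of its condition's planted
genes — real collections have per-study platform coverage gaps,
correlated effects across related studies, and messy nomenclature.
Recovery results on this world validate the pipeline's logic, not its
robustness to those artifacts.

## Numerical and reporting choices

- p-values in (0, 1]; underflowed hypergeometric tails clamp to 5e−324.
- Regulation matrix rows sorted lexicographically; ORA rows sorted by
  (p, term); pairwise tests by (p, label) — all outputs are permutation-
  invariant in input order.
- The report JSON is schema-versioned; timestamps are optional so reruns
  can be compared byte for byte.
- Stage failures abort with the stage name and persist a partial report
  listing the completed stages.

## Known limitations

- Recurrence counting trusts `study_id`; it cannot detect two manifest
  entries that are secretly the same experiment.
- Affinity propagation on > 15 fully tied terms falls back to greedy
  tie resolution, which may be suboptimal (never observed on non-
  degenerate similarity matrices in testing).
- The correlation test treats MeanRegDir values as continuous; with very
  few studies per condition the statistic is coarsely discrete and the
  t-distribution p is approximate.
- Only flat gene sets; no GO hierarchy-aware pruning of ORA results.
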