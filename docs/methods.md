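# Methods

## The activity index and XCI groups

For each female cell, allelic expression of the X chromosome is summarized
by the maternal fraction of SNP-informative reads pooled over X-linked
genes, f = Σ maternal / (Σ maternal + Σ paternal). The activity index
a = 1/max(f, 1 − f) maps f onto [1, 2]: a = 2 means both X chromosomes
contribute equally (XCI not begun), a = 1 means one X is fully silenced.
The index is symmetric in the two alleles and continuous at f = 0.5.
Cells are classified by half-open intervals — uninitiated (1.8 < a ≤ 2),
ongoing (1.2 < a ≤ 1.8), completed (1 ≤ a ≤ 1.2) — with boundary values
falling into the lower-activity group (a = 1.8 is ongoing, a = 1.2 is
completed). The bounds are configurable but default to these values
throughout.

Because a is a ratio estimate, cells with fewer than
`min_informative_reads` (default 50) X-linked allelic reads are flagged
`insufficient` and excluded from group percentages. The inactive allele is
the lower-expressed one per cell; at exactly f = 0.5 it is recorded
`undetermined` in the state table, and window profiling resolves the tie
to maternal by a logged convention. Xist and Tsix are excluded from f by
default: Xist is transcribed from the inactive X (and Tsix from the
active), so including them would bias the index; the exclusion list is a
parameter.

The maternal/paternal inactivation split is tested per condition with a
two-sided exact binomial test against 0.5, restricted to initiated
(ongoing + completed) cells — in uninitiated cells the choice of inactive
X is not identifiable. A binomial test is the natural test for an
allele-choice proportion; it is used here in place of a t-test whose
target quantity would be ambiguous.

## Chromosome-wide silencing profiles and escapees

X genes are ordered by start coordinate; genes with zero pooled allelic
reads in the analysed cell subset are dropped as uninformative. A sliding
window of 10 consecutive informative genes (step 1) pools inactive-allele
and active-allele reads across the subset's cells — each cell contributing
according to its own inactive-allele designation — and reports the ratio
Σ inactive / Σ active. Pooling before the ratio (rather than averaging
per-cell ratios) keeps windows stable at low counts; windows with zero
active reads are reported undefined. Fewer informative genes than the
window size yields a single whole-chromosome window with a warning.

For balanced cells the expected ratio is 1; for fully inactivated cells
without escapees the numerator is structurally 0. A gene is flagged as an
escapee when, pooled over completed-XCI cells, its inactive/active ratio
is ≥ `min_ratio` (default 0.1) and inactive-allele reads are detected in
≥ `min_cell_fraction` (default 0.25) of completed cells expressing the
gene. Both thresholds are surfaced in the configuration; they are
operational defaults, not biological constants.

## Allelic expression calls

A gene × cell pair is called from its read pair: an allele is detected at
≥ `min_allele_reads` reads (default 2); both detected → biallelic, one →
mono-maternal / mono-paternal, neither → undetected. The
expression-vs-allelic-pattern analyses are:

- per gene × condition allelic composition among cells expressing the gene
  at ≥ τ RPKM for τ ∈ {5, 10, 20};
- a one-sided Student's t-test per qualifying gene × condition (≥ 5
  biallelic and ≥ 5 monoallelic cells at τ = 20 RPKM) of whether RPKM is
  higher under biallelic expression, BH-adjusted across the table;
- for externally supplied up-/down-regulated gene lists between two
  conditions, the biallelic-fraction difference Δbi per qualifying gene
  (≥ 20 RPKM in ≥ 60% of either condition's cells) and, per direction
  group, an exact binomial sign test of whether genes with Δbi > 0
  outnumber those with Δbi < 0, ties dropped. The sign-test construction
  (per gene set, not per gene) is this package's declared interpretation
  and is stated in the output.

## Association analyses

The pluripotency score is the arithmetic mean RPKM of Pou5f1, Sox2, Nanog,
Klf2, Esrrb, Dppa3, Tcfcp2l1 and Prdm14 (missing genes are skipped with a
warning). Spearman correlations use average ranks; p-values come from the
exact permutation null for n ≤ 8 and the t-approximation above that —
enumerating larger factorials buys no accuracy at the p-values involved.
Per-gene cell filters (e.g. Xist ≥ 1 RPKM) restrict the correlated cells.
Marker enrichment runs one-way ANOVA on log2(RPKM + 1) — the log scale
stabilizes the within-condition variance of strongly expressed genes —
with BH adjustment, combined with an all-pairwise fold-change rule on raw
condition means with a 0.1-RPKM pseudocount; a gene can be enriched in at
most one condition. "Adjusted P" is Benjamini–Hochberg everywhere.

## The synthetic-data generator

The generator emulates count-level output of a C57BL/6J × CAST/EiJ cross.
Per female cell, a latent XCI degree d ∈ [0, 1] and an inactivated allele
(maternal with probability 0.7 under the preset) define the expected
maternal fraction of each X gene, p = 0.5(1 − d) + δd with δ ∈ {0, 1};
escapees use d scaled down by the retention factor (default 0.5).
Autosomes sit at p = 0.5; male cells emit maternal-only X reads; Xist is
drawn from the inactive and Tsix from the active X. Per gene × cell,
SNP-informative totals are Poisson around `mean_depth` scaled by a
log-normal per-gene base expression and the cell's modulation; maternal
counts are binomial (beta-binomial when `overdispersion` > 0); an equal
expected number of non-SNP reads tops up the total-count matrix, and the
library size scales the panel total by `library_scale` (default 40) so
RPKM values land where the 5/10/20 thresholds discriminate. Per-allele
dropout is Bernoulli with probability exp(−expected allele depth /
`dropout_scale`), producing monoallelic calls naturally at low expression.

Condition presets assign XCI-group mixture weights matching the observed
per-condition compositions (ground-state 2i: 70/30/0; serum/LIF ES:
54/40/6; delayed EpiStem: 24.1/50.6/25.3; EpiStem: 0/0/100; neurons:
10.3/17.9/71.8), plus four male conditions. Within a group, degrees are
drawn uniform over the central `spread` fraction of the group's degree
interval (d < 1/9, 1/9–2/3, > 2/3, the images of the activity bounds).
The default spread of 0.5 keeps group membership identifiable given
counting noise at a few thousand informative reads per cell; the
within-group spread is a free parameter of the generator, not an estimate.

Pseudotime t is coupled to d as t = clamp(d + N(0, `coupling_noise_sd`)),
so differentiation and XCI are globally correlated but asynchronous per
cell; pluripotency-module expression decays with t, differentiation-module
expression rises, with per-cell module noise (log-normal, σ = 0.5) large
enough that individual completed-XCI cells can outscore the
uninitiated-group median — the asynchrony property the association tests
check. Degrees are drawn from the condition mixture first and t derived
from d (rather than the reverse) so that the configured mixture weights
are exact group priors; the joint (d, t) distribution is the same either
way.

What the generator does not emulate: transcriptional bursting beyond the
dropout model, gene-length/GC biases, doublets, batch effects, real
genomic gene spacing (positions are uniform; only order matters to the
windowing), or Xist-coating kinetics. Passing tests therefore demonstrate
correctness of the estimators and decision rules under the stated
count model, not robustness to every artefact of real libraries.

## Numerical choices and degenerate inputs

- Zero informative reads → f and a are NaN, group `insufficient`.
- Windows with zero active reads → NaN ratio; genes with inactive-only
  expression get an infinite escapee ratio and are flaggable.
- Matrices are validated on construction: shared orderings, non-negative
  integers, maternal + paternal ≤ total, annotated genes only; violations
  raise errors naming the offending ids.
- All simulation randomness flows from a single `numpy` generator seeded
  by the config; identical seeds give identical datasets, and pipeline
  outputs are byte-identical for identical configs.
- Test and acceptance problem sizes (200–500 cells, 100–500 genes) are
  chosen so each property is measured with comfortable statistical margin
  while the whole suite stays quick on a laptop.

## Known limitations

- QC defaults (2000 genes at ≥ 1 RPKM; optional Nanog/Sox2/Pou5f1 ≥ 1 RPKM
  marker rule) are placeholders for dataset-specific thresholds, not a
  reproduction of any particular cell set.
- Sex inference assumes the hybrid-cross design (maternal-only X in males);
  it reports, but never overwrites, declared metadata.
- Differential-expression calling is out of scope: the biallelic-shift
  analysis takes externally produced up/down gene lists.
- Escapee detection is threshold-based on pooled ratios; it does not model
  per-gene overdispersion or test calibrated significance.
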