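# Methods

## Count model and differential expression

Counts are modeled as negative binomial with a log link:
`y_gs ~ NB(μ_gs, φ_g)` with `Var = μ + φμ²`, `log μ_gs = β_{g,group(s)}
+ log(L_s f_s)`, where `L_s` is the column sum (library size) and `f_s`
the TMM scaling factor. This is the parameterization used by mainstream
count-GLM tools, so φ estimates are directly comparable across
implementations (a well-replicated bulk RNA-Seq experiment typically
shows a common dispersion in the 0.01–0.05 range; the synthetic
generator's default of 0.0155 sits at the clean end of that range, the
regime these data represent).

**Filtering.** A gene is kept iff at least one of the six groups has
CPM ≥ 1.0 in at least two of its replicates. The threshold interprets
"a significant number of counts" as the conventional CPM ≥ 1 rule at
this library-size scale; both knobs (`cpm_threshold`,
`min_samples_per_group`) are exposed.

**Normalization.** TMM factors with the standard published trims (30%
on M-values per tail, 5% on A-values per tail), inverse-asymptotic-
variance weights on the kept M-values, reference column chosen as the
sample whose upper-quartile count fraction is closest to the mean upper
quartile, and a final geometric-mean-1 rescaling. Samples with fewer
than ten usable genes against the reference fall back to a unit factor.

**Dispersion.** The common dispersion maximizes the summed Cox-Reid
adjusted profile likelihood (APL) of the one-way group model: per gene,
group levels are profiled out by Newton steps on the one-dimensional NB
score, and the adjustment subtracts `½ log det` of the (block-diagonal)
Fisher information, which for a one-way layout is `½ Σ_groups log Σ_i
w_i` with `w = μ/(1+φμ)`. Gene-wise dispersions maximize the per-gene
APL by a vectorized golden-section search on log φ over
[1e-8, 5]. Tagwise values shrink gene-wise toward common on the log
scale with weights (residual df : prior df), prior df = 10 — a
deliberate one-step simplification of the three-step weighted-likelihood
empirical-Bayes scheme; it preserves the shrinkage contract (each
tagwise value lies between its gene-wise estimate and the common value)
without that scheme's tuning constants. Estimation refuses to run when
every group is a singleton.

**Testing.** Each contrast `c` (coefficients over group levels summing
to zero) is tested by a likelihood-ratio test: the full one-way model
against the model constrained to the null space of `c` (fitted by
batched Fisher scoring with the shared reduced design), at the tagwise
dispersions, referred to χ²(1) — one df because each contrast is a
single linear combination. The per-gene log2 fold change is the
contrast applied to `log2(normalized group mean + 0.5)`; the 0.5 offset
makes fold changes of zero-count groups finite and deterministic.
Bonferroni p is `min(1, m·p)` over the m tested genes; q-values are
Benjamini–Hochberg.

**DEG selection.** Two regimes, mirroring the two thresholds a
stringent bulk analysis uses: `glm_fwer` applies the fold-change
pre-filter |FC| ≥ 2 (inclusive) and then Bonferroni p < 1e-5 (strict);
`fc_q` applies |FC| ≥ 2 and BH q ≤ 0.01. Neither regime is privileged;
both are exposed because the appropriate one depends on downstream use
(pathway analysis favors the stricter FWER set).

Calibration note: with n = 3 per group the χ² reference for the LRT is
slightly liberal — null simulations at the default design show a
rejection rate of ~0.06 at nominal 0.05. At the selection thresholds
actually used (Bonferroni 1e-5, |FC| ≥ 2) this has no practical effect
on the selected sets (false positives are absent in the planted
simulations).

**MDS.** The distance between two samples is the root mean square of
the `top_genes` (default 500) largest absolute log2 fold changes
between them, on log2 CPM with a 0.5-count offset; coordinates come
from classical (Torgerson) scaling with a deterministic sign
convention. On the default synthetic design the first dimension
separates epithelial from mesenchymal groups.

## TF-target enrichment

For overlap `k` between a DEG set (size `n`) and a TF experiment's
target set (size `K`) in a universe of `N` genes:

* enriched: `p = P(X ≥ k)` (hypergeometric upper tail), fold ratio
  `(k/n)/(K/N)`;
* depleted: `p = P(X ≤ k)`, fold ratio `k_e/k` with `k_e = nK/N`,
  infinite when `k = 0`. The lower tail is the natural symmetric
  counterpart (the printed depleted ratios in the curated benchmark
  confirm the `k_e/k` convention).

Tail probabilities use scipy's hypergeometric survival/cumulative
functions, accurate to ~1e-300 and floored at the smallest positive
double. The Bonferroni multiplier is the number of experiments in the
loaded database (experiments on the same TF in different cell lines are
kept separate), not the number of distinct TFs; BH q-values are
reported alongside. DEG identifiers absent from the declared universe
are dropped from `n` with a logged count so (k, K, n, N) stay mutually
consistent. Significance: corrected p strictly below 0.01 and fold
ratio strictly above 1.5, sorted by fold ratio with ties broken by
experiment id. Fold ratios are kept at full precision; rounding to one
decimal happens only in display and benchmark comparison.

The curated benchmark (`emtseq/data/tf_enrichment_benchmark.tsv`)
carries 82 published enrichment/depletion records with n = 1,477 (up)
or 2,010 (down) and N = 23,284; every parseable record reproduces its
printed one-decimal fold ratio. One published record (the first
TP63 row of the down-regulated table) could not be parsed unambiguously
into (K, k) from the source rendering and is excluded.

**Bimodal overlap.** The overlap between the up- and down-enriched
experiment sets is tested with an upper-tail hypergeometric over the
experiment universe. Direct computation shows that the published
significance for 30 and 40 experiments sharing 18 (4.3e-13) corresponds
to the *strict* tail P(X > 18) over the 345-experiment universe
(P(X ≥ 18) gives 9.2e-12, and the 148-experiment universe gives
1.8e-5); both tail conventions are exposed (`tail="ge"` default,
`tail="gt"`).

## Peak-to-gene assignment

A peak targets a gene iff it overlaps, by at least one base on
half-open BED coordinates, the interval `[tx_start − upstream,
tx_end + downstream)` for plus-strand transcripts (mirrored for minus
strand). Defaults are 5 kb upstream / 1 kb downstream — the published
defaults of the PAVIS annotation convention this stage emulates — and
both windows are configurable. A peak may target several genes;
assignments from multiple transcripts of one gene are unioned; peaks
outside every window stay unassigned (counted and logged, no
nearest-gene rescue). Assignment is invariant to peak input order and
to coordinate mirroring.

## Clustering and permutation significance

Ward.D2 runs the Lance-Williams recursion on squared Euclidean
distances and reports square-root heights (scipy's `ward` on Euclidean
input follows exactly this convention); average linkage is UPGMA. Cuts
into k flat clusters are labeled A, B, C… in leaf order. Row z-scoring
uses the population sd and drops constant rows with a warning.

The permutation null shuffles every column independently, destroying
row correlation while preserving column marginals — the standard
clusterability null, chosen because the procedure being tested is
row/column agglomeration. "Dendrogram results" are summarized as the
distribution of merge heights; variance, skewness and kurtosis use
bias-uncorrected moment definitions (kurtosis is the raw `m4/m2²`) for
determinism. Empirical p is `(r+1)/(B+1)`, upper tail, never zero, with
minimum `1/(B+1)` at the default B = 1000. The test is one-sided
(upper) per statistic; the choice is deliberate — planted block
structure inflates all three statistics — and is surfaced in the
implementation.

For TF–target topology the clustered matrix is the signed membership
matrix: +1 where a DEG is an up-regulated target of an experiment, −1
for a down-regulated target, 0 otherwise, with TF experiments as
columns; membership with direction is the only datum both axes share.

## Synthetic-data generator

The generator emulates the six-group, triplicate EMT/TNF design:

* gene baseline means log-normal around `baseline_mean` (default 500
  expected counts, log-sd 1.0 — roughly the per-gene depth of a
  ~45 M-read library over ~23 k genes, scaled to simulation size, with
  a realistic one-decade spread);
* NB counts by the gamma-Poisson construction at dispersion φ
  (default 0.0155);
* library-size factors log-normal with CV 0.1 (matching the narrow
  scaling-factor range of a well-balanced experiment);
* planted DEGs (default 5% of genes, half up / half down) multiply the
  mean of every mesenchymal group (CM, T1M, T12M) by `2^±1.5`, making
  them differential along each M-vs-E contrast and separating the cell
  states in the MDS, as in the real design.

What the generator does **not** emulate: gene-length effects (no FPKM),
mean–dispersion trends, outlier genes, correlated genes, batch effects,
or a TNF time-course effect. Passing tests therefore demonstrate
correctness of the statistical machinery under the stated model, not
robustness to real-data pathologies such as dispersion trends or
composition shifts beyond what TMM's trims absorb.

TF databases are planted by exact (K, k) construction — k targets drawn
from the nominated DEG set, K−k from its complement — so the
(k, K, n, N) quadruples round-trip exactly through the enrichment
stage; null experiments draw targets uniformly. Peak fixtures place
gene models on one pseudo-chromosome (0-based half-open coordinates,
alternating strands, spacing wide enough that windows never overlap
neighbours) and cycle peaks through five placement categories with
known truth labels.

## Pipeline

`run_full` executes filter → TMM → dispersion → per-contrast LRT → DEG
selection → enrichment and depletion scans in both DEG directions →
optional peak annotation → TF-target topology clustering with
permutation significance → Venn comparison of the primary contrast with
the TNF contrasts. Every stage logs input/output dimensions and
failures abort with the stage name. Reports are TSV with provenance
headers (tool version, config hash excluding the output path, seed);
with fixed seeds reruns are byte-identical. Subcommands (`simulate`,
`filter`, `deg`, `enrich`, `annotate-peaks`, `cluster`, `compare`,
`run-all`) expose each stage independently.

## Problem sizes used in tests and the acceptance script

Simulation-based checks run at 2,000 genes × 18 samples (the full
six-group triplicate design), with 500 planted DEGs for the power
check; the TF-recovery check uses a 23,284-gene universe with 345
experiments (one planted at the published RELA scale, K = 1,147,
k = 152 against n = 1,477); clustering significance uses a 60 × 8
matrix at B = 1000 and null calibration 200 runs at B = 99. These sizes
give stable Monte-Carlo estimates while keeping the default suite quick
to run.

## Known limitations

* The dispersion shrinkage is a one-step log-scale weighted average,
  not the full three-step weighted-likelihood empirical-Bayes scheme;
  exact numerical replication of mainstream GLM tools' tagwise values
  is out of scope (their common-dispersion estimates agree closely).
* The LRT χ² reference is mildly liberal at n = 3 per group (see
  calibration note above).
* No FPKM computation: fold changes are count-based with TMM-scaled
  libraries. Analyses defined on FPKM fold changes are approximated by
  the `fc_q` regime on CPM-scale fold changes.
* Gene identity matching in program comparison is exact-id only; alias
  resolution and detection calls are the caller's responsibility (the
  common universe is an explicit argument).
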