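# Methods

## Overview

The pipeline asks two questions of a tumor/normal expression study: which
*pairs* of pathways show coordinated activity differences (cross-talk)
that discriminate the phenotypes, and which miRNAs plausibly regulate
those pairs. It is a fixed sequence of stages — differential expression,
pathway enrichment, per-sample pair scoring, cross-validated pair
selection, regulon inference and master regulator analysis — each exposed
as a library function, with a CLI and a pipeline driver on top.

## Differential expression

**Filtering.** Features whose mean across samples is strictly greater
than the q-quantile (default q = 0.25, linear-interpolation definition) of
all per-feature means are retained. Note that as q → 0 the interpolated
quantile tends to the minimum mean, so the minimum-mean feature is always
excluded by the strict inequality.

**Test.** Counts are scaled so every library equals the geometric mean
library size and rounded to integer pseudo-counts. Under NB sampling with
a common dispersion φ and equal libraries, the tumor-group total *a* of a
feature given the grand total *s* follows a beta-binomial law with shape
parameters n_t/φ and n_n/φ; the two-sided p-value sums the probabilities
of all outcomes no more likely than the observed one. As φ → 0 this
degenerates to the binomial conditional law of the two-sample Poisson
test, which is used directly when φ ≤ 1e−8 (the test suite verifies
agreement with the exact binomial test in this limit). The common φ is
estimated by maximizing the conditional log-likelihood over both groups
(coarse log-grid then bounded scalar refinement); the conditional
likelihood is independent of the per-feature means, which is what makes a
single shared φ estimable.

This is a deliberate simplification of quantile-adjusted conditional
maximum likelihood: the quantile-to-quantile adjustment of unequal
libraries is replaced by mean scaling to the geometric-mean library size.
It preserves the structure of the exact test and its Poisson/binomial
limits while remaining fully testable; tagwise/trended dispersions and
TMM normalization are out of scope.

**Calling.** log₂FC = log₂((mean_t + 0.5)/(mean_n + 0.5)) on normalized
means; the pseudo-count avoids infinities. DE requires |log₂FC| > 1
(absolute value — down-regulated features count) and BH-FDR < 0.01, both
strict.

## Pathway enrichment

One-sided (over-representation) Fisher exact p from the hypergeometric
upper tail, with the universe equal to the quantile-filtered gene set and
every pathway intersected with that universe first (sets below 5 genes
dropped). Significance is BH-adjusted p < 0.01 — the stricter reading
when both a raw-p cut and BH adjustment are in play. The test suite
checks the implementation against exhaustive integer-arithmetic
hypergeometric summation.

## Discriminating Score

Per sample, a pathway's activity is summarized by the mean M and sample
standard deviation S (ddof = 1) of its member genes' expression on the
log₂(x+1) scale of library-equalized counts; the log transform stabilizes
variance so S is comparable across pathways. The pair score is
DS = (Mₓ − M_y)/(Sₓ + S_y), kept signed (the downstream classifier is
sign-agnostic). If Sₓ + S_y = 0 the score is 0 when the means agree and a
logged ±1e6 cap otherwise, keeping the matrix finite. Columns cover all
C(P, 2) unordered pairs in lexicographic "x|y" order. The Euclidean
comparator is implemented as the 1-D distance |Mₓ − M_y| between the two
activity summaries — one interpretation of a pathway-level Euclidean
metric, labeled as such; it equals |DS|·(Sₓ+S_y) wherever spread is
positive.

## Pair selection

Stratified 60/40 Monte Carlo splits (stratification keeps class
proportions stable under imbalance), 50 bootstraps by default. Each pair
is ranked by the mean out-of-fold AUC of a single-feature random forest
(500 trees, mtry = √1 = 1, stratified 10-fold CV); ties break
lexicographically by pair name for reproducibility. The top-10 pairs per
bootstrap are refitted on the whole training partition and validated on
the held-out samples (ranking uses the training AUC only; test AUC is
reported, not used for ranking). Aggregation counts, per pair, the
bootstraps in which it entered the top-10.

Two feature modes exist: *full-pipeline* mode recomputes
DEA → PEA → DS from the training samples of each bootstrap, so feature
construction never sees test data; *fixed-feature* mode ranks a
precomputed DS matrix and is the fast path for unit tests and for
exploratory runs. Randomness is governed by one master seed that spawns
independent per-bootstrap streams, so results do not depend on execution
order. The same machinery applied to raw expression rows
(`baseline_classifier`) provides the TF- and miRNA-expression baselines.

## Regulons and master regulators

**MI estimator.** KSG algorithm 1: MI = ψ(k) + ψ(n) − ⟨ψ(nₓ+1) + ψ(n_y+1)⟩
with max-norm joint neighborhoods and strictly-within-radius marginal
counts, k = 3 by default (standard low-bias choice at typical cohort
sizes). Count data are full of ties, which break k-NN counting, so
seeded uniform jitter of relative scale 1e−10 is added before the search.
Two implementations of the identical estimator are used: a cKDTree path
for long vectors and a vectorized distance-matrix path for n ≤ 600
samples (the common case when scanning thousands of miRNA–gene pairs);
they agree up to tie-breaking noise, and the test suite cross-checks them
and calibrates the estimator against the bivariate-Gaussian closed form
−½ln(1−ρ²).

**Regulon rule.** MI alone does not give a target list, so the default
rule builds a per-miRNA null by shuffling the miRNA's sample order
(5 permutations, pooled across genes), converts each observed MI to an
empirical upper-tail p with add-one smoothing, applies BH across genes
and keeps FDR < 0.05. A `top_k` alternative is exposed. No sign
constraint is imposed (MI is unsigned), matching an MI-only protocol.

**MRA.** For a pathway pair (a, b), each miRNA's regulon is tested for
Fisher over-representation in a and in b within the enrichment universe;
p-values are BH-adjusted across miRNAs separately per pathway (adjusted,
not raw, p < 0.01 on both sides — the self-consistent strict reading),
and the master-regulator flag additionally requires the miRNA to be
differentially expressed.

**Delta index.** (ex_tumor − ex_normal) × log₂FC per DE miRNA; positive
exactly when the expression-change direction agrees with the fold-change
sign. The published worked examples are reproduced to within the 0.5%
rounding tolerance of their two-decimal inputs.

## Synthetic studies

The generator emulates the data regime the pipeline targets and gives
every stage a recoverable ground truth:

- **Counts.** NB via gamma–Poisson mixture, mean–dispersion
  parameterization with one common φ (default 0.1, a typical bulk RNA-seq
  value); per-gene baseline means are log-normal (median 100, σ = 1) to
  emulate sequencing dynamic range; miRNA baselines use σ = 0.7 because
  with plain total-count normalization a single very abundant shifted
  miRNA would distort library sizes at desk-scale miRNA counts.
- **DE genes.** `n_de_genes` genes get tumor means scaled by
  2^(±planted_logfc), alternating sign.
- **Pathways.** Enriched pathways draw 60% of their members from the DE
  pool; background pathways sample genes uniformly (the enrichment null).
  Cross-talk pairs share `overlap_fraction` of the smaller pathway's
  size.
- **Cross-talk planting.** The non-overlap genes of one pathway of each
  pair get an additional coherent +0.8 log₂ shift in tumor samples only:
  below the DE cut of 1, so the pair's DS separation is carried by the
  coordinated pathway-mean shift rather than by extra DE genes.
- **Regulons.** One regulator miRNA per cross-talk pair, DE (up in
  tumor), with `regulon_size` targets drawn from both pathways. A shared
  latent factor h ~ N(0,1) per sample couples them: targets load
  +√strength on h, the miRNA loads −√strength (sign configurable), and
  latent values map to each feature's own NB marginal by quantile
  transform. Every miRNA–target pair therefore has latent correlation of
  magnitude `regulon_strength`; coupling to a mean of targets instead
  would dilute per-target dependence by 1/√regulon_size and make
  single-gene MI detection scale-dependent.

What the generator does **not** model: batch effects, library-size
heterogeneity (all libraries have equal expected depth), isoform-level
miRNA quantification, correlated background genes, and indirect
regulation. Consequently, passing recovery tests show the pipeline's
stages compose correctly and are sensitive at realistic effect sizes —
not that the method is robust to cohort-level confounding in real data.
Note also that MI-based regulons cannot distinguish direct targets from
genes correlated through the phenotype; the dependence-only recovery test
(no DE planting) isolates the estimator from that confounder, and
data-processing-inequality pruning is deliberately out of scope.

## Test and validation configurations

Simulated checks run at desk scale, chosen once as realistic for the
regime (tens of samples per class, hundreds of genes):

- **Null control:** 20 seeds × (300 genes, 12+12 samples, φ = 0.1, no
  planted signal); total DEG count must stay within the nominal
  FDR bound; pair AUCs on a 400-gene null study must center on 0.5.
- **Planted recovery:** 10 seeds × (800 genes, 60 miRNAs, 8 pathways of
  12–24 genes, 60 DE genes at logFC 2.5, 2 cross-talk pairs, regulon
  size 12 at strength 0.8, 30+30 samples), selection with 8 bootstraps,
  5-fold CV, 50 trees. ≥90% of seeds must place a planted pair in the
  aggregated top-10 and flag every planted regulator as a master
  regulator.
- **Estimator calibration:** KSG at n = 2000, k = 3 against the Gaussian
  closed form (±0.05 nats) and the independence null.

## Numerical choices and degenerate inputs

- BH is implemented directly (step-up with cumulative minimum from the
  largest rank) and oracle-tested against the textbook rule.
- The exact-test outcome sum uses a (1 + 1e−9) relative slack when
  collecting outcomes "no more likely than observed", guarding against
  float ties in the pmf.
- Constant features: AUC 0.5 with a warning; constant vectors: MI 0 with
  a warning; pathways with <2 genes present: dropped with a warning,
  error if none remain.
- A bootstrap whose training data yield fewer than two enriched pathways
  falls back to the two best-ranked pathways (logged), keeping the
  bootstrap comparable rather than aborting the run.
- All file formats round-trip through their own readers; the pipeline
  manifest records the SHA-256 of every artifact, and identical
  config + seed reproduce byte-identical manifests.

## Known limitations

- Total-count library normalization is composition-sensitive; strongly
  asymmetric DE can shift logFC estimates (TMM-style robust scaling is
  out of scope).
- The exact NB test's integer rounding of pseudo-counts discards
  sub-count information; with very small libraries this loses power.
- The per-pair single-feature RF ranking ignores interactions between
  pairs; it ranks pairs marginally, as the protocol specifies.
- KSG MI on heavily tied, low-count features is jitter-sensitive;
  estimates for near-constant features should not be over-interpreted.
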