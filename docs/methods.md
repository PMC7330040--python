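# Methods

This note documents the models, parameter choices and numerical
conventions behind `tmenet`, and what the synthetic cohort does and does
not establish about real data.

## Co-expression network and modules

The network is built on a genes × samples log2 expression matrix.  For
raw counts, `filter_and_normalize` first removes genes with fewer than 5
counts in ≥ 80 % of samples, log2(x+1)-transforms, quantile-normalizes
every sample to the mean empirical distribution (ties receive the mean of
the reference values they span), and then keeps genes with normalized
signal > 5 in ≥ 80 % of samples as network substrate.

Adjacency is unsigned, `a_ij = |cor(x_i, x_j)|^β` with β = 6.  An even
power makes the sign of the correlation irrelevant, so the unsigned form
is the natural reading of "correlation raised to the sixth power"; a
signed variant `((1+cor)/2)^β` is available behind the `signed` flag and
off by default.  The adjacency diagonal is zero (so connectivity is
`k_i = Σ_j a_ij`); the TOM diagonal is one.  These conventions are stated
here once and enforced everywhere.

The topological overlap measure is the unsigned Zhang–Horvath form

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),
    l_ij = Σ_{u≠i,j} a_iu a_uj.

Because the diagonal is zero, the matrix product `A·A` computes `l`
without explicit index exclusion; the result is symmetrized against
floating-point round-off and clipped to [0, 1].

Module detection uses average-linkage hierarchical clustering on
`1 − TOM` with a **static** tree cut (default `cut_height` 0.99,
`min_module_size` 30).  Dynamic tree cutting is deliberately not
reimplemented: the static cut is simpler and fully deterministic, and the
merge step below is the quantitatively specified part of the procedure.
This is the main place where module counts can differ from analyses that
use dynamic cutting; the merge threshold, not the cut, is the contract.
Clusters below the minimum size receive the reserved label
`"unassigned"` (the grey-module convention).  Labels are a pure function
of the partition: modules are named GM1, GM2, … by decreasing size, ties
broken by the lexicographically smallest member gene.

Modules whose eigengenes satisfy `1 − cor(ME_a, ME_b) < 0.10` are merged
iteratively (closest pair first, eigengenes recomputed after every
merge); the loop terminates because the module count strictly decreases.

The scale-free criterion bins connectivity into 10 equal-width bins and
regresses log10 relative frequency on log10 mean connectivity.  At least
two non-empty bins are required rather than ten distinct connectivity
values: exact power-law grids (the natural test input) concentrate many
genes on few distinct values.

## Eigengenes and trait statistics

A module eigengene is the first principal component of the member genes'
standardized expression, computed by SVD, re-standardized to mean 0 / sd 1
across samples, and sign-oriented so the mean member correlation is
non-negative (exact-zero ties orient the first non-zero coordinate
positive).  Standardizing to sd 1 rather than unit norm changes no
correlation or test statistic but makes group contrasts scale-free.
Single-member modules degrade to the standardized gene with a warning;
constant member genes are dropped.

Module–trait association is the Pearson correlation of eigengene and
trait with the two-sided t-distribution p-value on n − 2 df (asymptotic,
not permutation — the conventional choice; eigengenes and binary traits
at cohort sizes of tens of samples are well inside its validity range).
Group contrasts use Welch's t (unpaired) or the paired t matched by
patient id, which errors on orphaned patients rather than silently
dropping them.  All FDRs are Benjamini–Hochberg across modules (per
trait).  Eigengene dendrograms append the standardized trait as a
pseudo-eigengene and cluster `1 − cor` by average linkage.

External scoring recomputes eigengenes from the member genes present in
the external matrix; missing members are dropped, never imputed, and a
per-module coverage fraction is reported so transferability can be
judged.  Modules with fewer than 2 surviving members are skipped.

## Module annotation

Cell-type enrichment scores each module in purified reference profiles
as the **mean standardized member expression** per profile, not a
re-fitted PC-1: reference panels have few profiles (the emulated design
has 4 per cell type), where PC-1 is unstable.  Scores are compared across
cell types by one-way ANOVA with BH FDR, and the top-scoring cell type is
reported.

Signature overlap uses the size-corrected statistic
`100·|module ∩ signature|/|module|`.  Its null is built from random gene
sets of the signature's size drawn uniformly from the universe (default
1,000 draws, seeded); the null mean/sd feed the hollow-bar display.  The
p-value tests the 2×2 membership table with a chi-square test without
continuity correction; Fisher's exact test is available behind a flag
(both tests are in circulation for this statistic; chi-square is the
default for the overlap display).  The universe defaults to all network
genes and is overridable.

Over-representation of a hit list is the upper-tail hypergeometric
probability; the ranked-list mHG score is `min_n HGT(n)` over all
prefixes, with its p-value estimated by seeded rank permutations with the
add-one correction (smallest attainable p = 1/(n_perm+1)).  The exact
dynamic-programming mHG bound is not implemented; permutation is
assumption-free and reproducible.

Intramodular connectivity `kIM(g)` sums a gene's TOM to its module mates;
rank 1 is the hub, ties broken by gene id.  Unassigned genes get NaN.
Hub neighborhoods return the top-TOM members per module around a focal
gene, and a global top-quantile edge list supports network rendering.

## Copy number and somatic variants

Coordinates are 1-based fully-closed throughout (SEG convention); a
converter is provided for half-open BED input.  Segment–gene overlap is
any shared base — no minimum-overlap rule.  Per sample × gene, the copy
number most deviating from 2 among overlapping segments is selected and
mapped through deletion (< 1.0), loss ([1.0, 1.85)), diploid
([1.85, 2.15]), gain ((2.15, 4.0]) and amplification (> 4.0); any
overlapping segment with CN < 1.0 forces deletion regardless.  A tie at
equal deviation on both sides of 2 resolves to the lower copy number
(conservative toward loss; logged).  Overlapping segments within one
sample are a hard error; uncovered genes produce no call and are counted
in the log.

The SNV cascade applies, in order: tumor supporting reads ≥ 8, normal
supporting reads ≥ 6, tumor VAF ≥ 0.1, normal VAF ≤ 0.1, somatic Fisher
p ≤ 0.05, variant-base distance from read end ≥ 5, then base-quality,
mapping-quality and strand-bias screens.  All thresholds are
boundary-inclusive.  The three screens require read-level data this
package does not model; they are consumed as precomputed per-site
p-values, and a site passes a screen when p ≥ α (α = 0.05): a significant
screen result flags an artifact.  Records missing a screen p-value are
`not_evaluable` — never passed.  The audit attributes each rejection to
the first failing rule, so rule counts sum to
input − passed − not_evaluable.  The "supporting reads in normal" field
is deliberately named `n_supporting` without committing to alt- or
reference-supporting semantics; callers differ, and either can be
supplied.

Severity ranks consequences 1–4: missense < inframe indel < splice <
frameshift = nonsense; anything outside this ordering (synonymous,
other) ranks 0, and per-gene summaries keep the maximum.  Group
alteration frequencies (any passing non-synonymous mutation, optionally
plus amplification/deletion calls) are tested per gene with the
two-sided Fisher exact test and BH FDR.  Concordance between matched
samples counts identical (chrom, pos, ref, alt) keys:
shared/(shared + a_only + b_only).  Mutation profiles are binary
sample × site vectors clustered by average linkage on Jaccard distance;
a sample with no variants sits at distance 1 from everything.

## Differential expression and outcome

The differential-expression stage is a Welch/paired-t contrast on log2
expression with the conventional DEG rule (BH FDR < 0.05 **and**
|log2 FC| ≥ 1).  It is not a negative-binomial count model, and DEG
counts will differ from count-model engines; the fold-change gate is
independent of significance by design.  Genes constant in both groups
get p = 1 and are flagged.

Module scores are dichotomized at the cohort mean (strictly-above →
High; values exactly at the mean → Low, a documented tie rule; constant
scores error).  Survival uses Kaplan–Meier product-limit curves and the
two-group log-rank test (hypergeometric variance at each event time,
simultaneous-event tie convention), delegated to `lifelines`.  Zero
observed events is an error ("log-rank undefined"), as is a missing
group.  No Cox or multivariable modeling is provided.

## Synthetic cohort

The generator emulates the statistical skeleton of a matched-trio
colorectal cohort.  Defaults (all overridable, chosen once):

* **Genes/modules:** 2,000 genes; five planted modules of 300, 250, 200,
  150 and 100 genes plus 1,000 background genes.
* **Samples:** AN 8, CNM 12, CWM 22, CLM 22 (64 total); every CWM/CLM
  index pair shares a patient, the first 8 patients form full trios with
  an AN sample.  Metastasis trait = 1 for CWM and CLM.
* **Expression:** member gene = base + λ·f_m + ε with base ~ U(6.5, 10)
  log2 units, loadings λ ~ U(0.7, 0.95) and noise sd 0.5 — expected
  within-module correlation λ²/(λ² + σ²) ≈ 0.65–0.78, typical of module
  cores in this kind of analysis.  Background genes are pure noise
  (sd 0.8); 15 % of them are drawn at low baseline (U(0, 2)) so the
  count filter has real work.  Module 1's factor is shifted +1.5 sd in
  CWM and CLM (the planted metastasis program).
* **Counts:** Poisson(library × (2^expression − 1)) with lognormal
  library factors (sd 0.2) — a depth model, not a dispersion-calibrated
  RNA-seq simulator.
* **References:** 4 cell types × 4 profiles; fibroblast/endothelial/
  leukocyte profiles elevate modules 1/2/3 by +2 over N(0, 1) noise
  (emulating FACS-purified panels).
* **Signatures:** per mapped module, 50 % of members plus 50 random
  background genes, and one fully random control signature.
* **Genome:** three chromosomes (120/100/80 Mb) tiled per tumor sample
  by exponential segments (mean 8 Mb) with category probabilities
  deletion/loss/diploid/gain/amplification = .05/.15/.50/.20/.10 and CN
  drawn uniformly within each band; ~2,000 gene models of 20–150 kb are
  placed independently, so a realistic fraction straddles segment
  boundaries.
* **Variants:** ~60 per tumor sample.  For a concordance parameter c and
  per-sample count n, matched pairs share s = n·2c/(1+c) sites so that
  the measured concordance s/(s + 2(n−s)) equals c exactly; shared sites
  reuse one set of filter-field draws on both sides (same DNA context),
  so filtering removes them symmetrically and preserves c.  Each filter
  rule is violated independently with probability 0.02.  A designated
  driver gene (the first background gene) carries a guaranteed-passing
  missense mutation with group-dependent probability (CNM 0.5,
  CWM/CLM 0.05), emulating a group-enriched mutation for the Fisher
  stage.
* **Survival:** exponential event times with hazard
  0.025·exp(0.9·ME₁) per month (median ≈ 28 months at baseline) and
  independent exponential censoring calibrated to ≈ 30 % at the
  baseline hazard; censoring rate 1 censors every record.

Everything is drawn from one seeded `numpy` Generator: identical
config + seed gives bit-identical cohorts.

**What passing tests show — and don't.**  The generator plants linear
one-factor blocks with Gaussian noise, independent background genes, and
exactly exponential survival.  Real tumor expression has correlated
background structure, nested and overlapping programs, batch effects,
compositional (tumor-purity) confounding and count overdispersion, none
of which are modeled.  Recovery of planted modules at ARI ≥ 0.8 and
calibration of the statistical stages under this null therefore validate
the implementation, not the biology; module counts and specific gene
lists from real cohorts are expressly not reproduction targets.

## Numerical choices and degenerate inputs

* Correlations are clipped to [−1, 1] before powering; TOM is
  symmetrized and clipped to [0, 1] after the matrix products.
* SVD-based eigengenes resolve the sign ambiguity via the member-
  correlation orientation rule, making repeated runs identical.
* Zero-variance genes are dropped with a log entry at adjacency and
  eigengene stages — never silently.
* Chi-square overlap tests fall back to p = 1 on degenerate (zero-margin)
  tables; ANOVA on identical group values reports F = 0, p = 1.
* Problem sizes in the test suite are scaled to what the statistics
  need: exact oracles run on ≤ 25-gene matrices and ≤ 40-count tables,
  recovery and calibration studies use the 2,000-gene default cohort or
  reduced replicas (500 replicates for null-calibration checks, 100
  seeds for trait-linkage recovery), and the chi-square calibration uses
  large membership tables where the asymptotic test is valid.

## Known limitations

* Static tree cut instead of dynamic tree cut (above).
* The DE stage is a t-test stand-in, not a count model.
* mHG significance is permutation-based, not the exact bound.
* The three read-level variant screens are consumed, not computed.
* No GO DAG semantics: gene sets are flat lists (GMT).
* No cell-fraction deconvolution: modules are overlapped with signature
  lists, not decomposed into mixtures.
* Log2-ratio copy-number conventions (e.g. "deep deletion ≤ −2") are a
  display convention only; the absolute-CN thresholds above are
  canonical throughout.
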