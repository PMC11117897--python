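# Methods

This note records the models behind each pipeline stage, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical decisions that matter when reading results.

## Stratification

A patient is Phen1 iff both criteria hold:

* **HC criterion** — at least one physician-documented head-circumference
  measure with `age_months <= 24` and `percentile >= 75`. Both boundaries
  are closed: a measure taken exactly at the second birthday counts, and the
  75th percentile itself qualifies (the criterion is "at or above"). Records
  with no in-window documented measure are `undocumented` and leave the
  funnel.
* **Flare criterion** — at least one behavioural-worsening event whose
  trigger is an immune challenge (`fever`, `infection`, `vaccination`,
  `tooth-loss`, `acute-inflammation`). A stricter reading — every
  immune-challenge episode must worsen symptoms — is available via
  `flare_criterion(..., systematic=True)` but is not the default, because
  the one-event rule is what the funnel arithmetic operationalises.

The prevalence denominator is every patient for whom *both* criteria were
assessable: flare-assessable HC ≥ 75 patients plus documented HC < 75
patients. HC < 75 patients are treated as flare-assessable unless their
record flags otherwise; that convention is what makes the funnel arithmetic
close (the assessable pool is the HC ≥ 75 assessable count plus all
documented HC < 75).

The genetic exclusion screen uses a packaged 83-gene ASD panel; any
non-clear screen excludes, and an unscreened record is flagged rather than
silently passed (policy configurable: flag or error).

Comparison-group selection (`select_non_phen1`) stratifies eligible patients
(documented maximum HC percentile < 75) into the terciles [0, 25), [25, 50),
[50, 75) and samples one third from each; when n is not divisible by 3 the
remainder goes round-robin starting at the lowest tercile — an arbitrary but
fixed rule.

## Negative-binomial differential expression

Technical replicates are summed per subject (summing preserves the NB family
and the total library counts). Size factors are median-of-ratios over genes
expressed in every subject, rescaled to geometric mean 1 so a single-subject
matrix gets factor 1.

Per gene, counts follow `NB(mu, alpha)` with
`log mu = log s_j + b0 + b1 * x_j`. Because the only covariate is the group
indicator, the MLE separates by group and each group mean solves the
one-dimensional score equation `sum_j (y_j - s_j m) / (1 + alpha s_j m) = 0`
(Newton on log m, vectorised across genes; step clipped to ±2, 50-iteration
cap, convergence at 1e-10). The log2 fold change is the log-ratio of group
means; its Wald standard error comes from the per-group Fisher information
`sum_j mu_j / (1 + alpha mu_j)`.

Dispersion: the method-of-moments estimate uses pooled within-group
variances of normalised counts, `alpha = (s² − z·mu)/mu²` with `z` the mean
reciprocal size factor, clipped to [1e-8, 10]. A `a0 + a1/mu` trend is
fitted by non-negative least squares with two trimming passes (drop genes
whose ratio to the fit leaves [0.01, 10]), and gene-wise estimates are
shrunk toward the trend in log space with weight 0.5.

Two small-sample choices keep the test calibrated at the 10 + 10 design:
the shrinkage above, and referring the Wald statistic to a t distribution
with `n_subjects − 2` degrees of freedom instead of the normal. On pure-null
simulations (5,000 genes, 10 vs 10 subjects, two technical replicates) the
empirical type-I error at nominal 0.05 sits near 0.04 and the p-value
distribution is consistent with uniform; the acceptance suite re-measures
this on every run. Genes with zero counts everywhere are reported as NaN and
excluded from testing and from the BH adjustment. Numeric parity with any
external DE implementation is a non-goal; a cross-check against pydeseq2 on
a small simulation (fold-change correlation > 0.95) guards against gross
disagreement.

The ranked signature filters on *raw* collapsed counts — median across
subjects strictly greater than 10 reads (a median of exactly 10 is
excluded); filtering on normalised counts is available by flag. Remaining
genes are sorted by log2FC descending, ties broken by smaller p-value then
gene identifier, so output is deterministic. The up/down query sets are the
first and last k (default 250).

## Classifier validation

PCA for classification runs on `log2(normalised count + 1)`, columns centred
but not scaled, on the chosen gene subset; subjects are scored on the first
two components. The LOOCV logistic classifier is a Newton/IRLS fit of an
intercept + 2-feature model with a fixed tiny ridge (1e-6) so the Hessian
stays invertible under quasi-separation; all n leave-one-out folds are
solved as a batched Newton iteration, which is what makes 1,000-shuffle
permutation tests take fractions of a second. Linear predictors are clipped
at ±30 inside the sigmoid; held-out classification thresholds at 0.5. On
non-separable data the fold-wise predictions match scikit-learn's
near-unpenalised logistic regression exactly (tested).

The permutation p-value is the add-one estimator
`(1 + #{null >= observed}) / (1 + B)`, which can never be zero and is always
valid. Because LOOCV accuracy on n subjects takes only n + 1 values, ties
between null scores and the observed score are heavy, and the add-one
estimator is therefore *super-uniform* under the null (conservative, mean
above 0.5) — a structural property of discrete permutation tests, not a
bug. For calibration diagnostics the report also carries a randomized
tie-broken p-value, `(#{null > obs} + U·(1 + #{null == obs}))/(1 + B)` with
`U ~ Uniform(0,1)`, which is exactly uniform under label exchangeability;
the test suite checks uniformity of the randomized version and validity
(non-anti-conservatism) of the reported one.

## Enrichment

The enrichment statistic is two-sample: target rank positions against
non-target positions, walking the ranked list from the most up-regulated
gene and tracking the difference between the two ECDFs. The ES is the
deviation of largest magnitude with sign fixed so ES > 0 ⇔ targets
concentrate among up-regulated genes; the scan uses integer arithmetic
scaled by `m·n` so the ±1 limits are exact. The p-value is the two-sided
two-sample KS probability (exact enumeration when the domain has ≤ 30
genes, asymptotic otherwise). By default the domain is the union of the up
and down query sets in log2FC order — the 500 genes the signature actually
nominates — with the full ranked transcriptome available via
`domain="full"`; the choice matters and is surfaced in every result object
through `n_signature`.

Fisher over-representation uses the exact conditional hypergeometric
p-value, the sample cross-product odds ratio, and a log-OR normal 95% CI;
a zero cell yields an unbounded CI with a warning rather than an error.

## DGES drug scanning

Merging: each cell line's weight is `max(0, mean Spearman correlation with
the other lines)`, renormalised; all-zero weights (or a single line) fall
back to uniform. Since per-cell-line rankings are permutations, Spearman is
computed as Pearson on ranks. The merged list orders genes by weighted
average rank, ties broken lexicographically. The score is
`(ES_up − ES_down)/2` with the same signed ECDF scan as the enrichment
module — the simplest rank-based combination that makes
`dges(drug, down, up) = −dges(drug, up, down)` an exact identity, which the
reversal construction requires. Library z-scores use the population standard
deviation (so they have mean 0, sd 1 exactly), p-values are two-tailed
standard normal, and the scan emits percentile ranks, a top-1% flag and
boxplot summary statistics (Q1/median/Q3, whiskers at 1.5 × IQR) for
reporting. Standardisation is per query and per library: observed and
reversed scans are standardised separately.

## Metabolic plates

The NADH proxy is `A590 − A750` per well (dye peak minus background).
Background filtering is a one-sided Welch t-test of cell values against
no-cell blank values per compound at alpha 0.05 — the removal rule for
compounds "similar to blank" is not standardised anywhere, so a documented
test with a tunable level is used; its false-keep rate is re-measured on
null plates in the acceptance suite. ANOVA + Tukey HSD (Tukey–Kramer for
unequal group sizes) handles per-compound group contrasts; the Tukey
p-values are verified against an R `TukeyHSD` oracle and an independent
studentized-range assembly. PCA defaults to correlation mode (compounds have
heterogeneous dynamic ranges) with covariance mode by flag; contributions
are squared loadings normalised per dimension. Dose-response curves divide
by the zero-dose baseline (so the baseline is exactly 1) and test for a
trend by one-way ANOVA across dose levels, falling back to a regression
slope test when dose levels lack replication.

## Synthetic data

The generators define the conditions under which the pipeline is validated.

* **Cohort** — default probabilities are the funnel's stage-to-stage
  proportions (89/313, 46/89, 41/46, 20/41). Fixture mode hard-wires the
  strata sizes (313/89/46/41/20, with all 43 documented HC < 75 patients
  assessable) and randomises only within-stratum attributes, so the funnel
  arithmetic is reproduced exactly while records stay individually
  plausible. HC is generated directly as a percentile; no growth-chart
  modelling.
* **Expression** — 5,000 genes, 10 + 10 subjects, two technical replicates,
  baseline means log-uniform over 10^0.5–10^3, dispersions log-uniform over
  0.05–0.5, per-sample library factors uniform 0.7–1.4, and a planted
  100-gene TF-target set at log2FC N(2, 0.3) — the design point at which
  recovery and calibration are asserted. Technical replicates are i.i.d. NB
  redraws from the subject-level mean (not multinomial thinning), so summing
  them is the correct collapse. There are no subject-level random effects,
  batch effects or outliers, so passing tests show correctness of the
  machinery at the stated design, not robustness to real-data pathologies.
* **Drug library** — 2,100 drugs × 3 cell lines over a 978-gene universe.
  The planted reverser's latent score is
  `strength·t + (1 − strength)·N(0,1)` with t = +1 on disease-down genes and
  −1 on disease-up genes (mimicker: −t); each cell line adds `N(0, noise_sd)`
  before ranking, ties broken by gene id, so `strength=1, noise=0` orders
  the sets deterministically.
* **Plates** — per-group compound shifts default to the study's structure
  (Phen1 down ~0.15 on sugars/sugar phosphates, up ~0.15 on
  adenosine/inosine/mono-methyl succinate; milder non-Phen1 sugar deficit),
  group sizes default to 20/19/17 cell lines, and the PM-M6 row-A db-cAMP
  series has a positive slope (0.35 across the log-dose range) only in the
  Phen1 group. The packaged plate layouts are synthetic PM-M-style layouts
  (named compounds placed among generic fillers; one blank column); real
  layouts can be supplied as CSV.

All generators draw from a single seeded `numpy` generator per call; the
same seed and config reproduce outputs exactly.

## Known limitations

* The DE engine targets two-group designs only; no covariates, interaction
  terms, fold-change shrinkage or outlier refitting.
* Genes expressed in only one group get large finite fold changes limited by
  the 1e-8 mean floor; interpret extreme log2FCs of near-zero-count genes
  with care.
* The KS p-value is asymptotic for domains larger than 30 genes and ignores
  the selection step that built the ranked domain.
* DGES treats drug rankings as exchangeable permutations; treatment
  duration, dose and cell-line identity beyond the merging weights are out
  of scope.
* The plate module analyses endpoint reads only; no kinetics, no
  plate-reader file parsing.
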