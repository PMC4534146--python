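# Methods

This note documents the models, parameter choices and numerical decisions
behind `dcis_cna`, and what the synthetic-data tests do and do not
establish about real tissue-microarray data.

## FISH scoring model

A sample-locus measurement is a list of per-cell counts for one test probe
and two control probes (3q25, 2q37).  The package treats the published
scoring criteria as a deterministic decision rule with six parameters
(`CallParams`):

| parameter | default | meaning |
|---|---|---|
| `gain_ratio_threshold` | 1.5 | pooled test/control ratio above which a sample is gained |
| `gain_signals_per_cell` | 3 | mean test signals per cell above which a sample is gained |
| `deletion_ratio_threshold` | 0.75 | ratio below which a sample (or cell) is deleted |
| `heterogeneity_fraction` | 0.25 | cell fraction for the cell-level deletion rule and the heterogeneity flag |
| `min_cells` | 40 | minimum scorable cells; below it the call is `no_signal` |
| `target_cells` | 100 | cells aimed for when scoring (documentation only) |

Decisions that the criteria leave open, resolved here as package policy:

- **Pooling the two controls.**  The pooled ratio divides the test total
  by the *mean* of the two control totals.  A strict mode
  (`strict_controls=True`) instead requires the gain/deletion inequality
  against each control total separately; it is never the default because
  the single published ratio suggests one denominator.
- **"More than three signals per cell"** is read at sample level as the
  mean test signals per scored cell (the rule describes case-level
  scoring); the per-cell version (`test_count > 3`) feeds the per-cell
  statuses used for heterogeneity and cell-fraction deletion.
- **Heterogeneity** is the minority fraction of the per-cell gain /
  non-gain partition reaching 25 %; "a different signal call" is not
  otherwise specified.
- **Cells with no control signal** cannot contribute a ratio; they are
  excluded from all ratio computations but retained in the
  signals-per-cell mean (and can trigger the per-cell gain rule through
  their test count alone).
- **Gain precedence.**  When the cell-fraction deletion rule and the
  signals-per-cell gain rule both fire, the call is `gain`.
- All threshold comparisons are strict, so a pooled ratio of exactly 1.5
  is not a gain and exactly 0.75 is not a deletion.

## Gain categories

The mutually exclusive category is computed over the three risk loci only
(HER2 is assayed identically but never enters the category): a sample with
any unevaluable risk locus is `unable_to_determine`; otherwise the set of
gained loci maps to no-gains / single-locus / two-of-three / all-three.
Deleted calls count as "not gained" — the association analyses concern
gains, and deletions at these loci are rare.

## Contingency statistics

Sensitivity, specificity, PPV and NPV are percentages with missing (NaN)
values, never zeros, when a denominator is empty.  The two-tailed Fisher
exact test uses the probability-mass rule — the sum over all tables with
the observed margins whose hypergeometric probability does not exceed the
observed table's (relative tolerance 1e-7) — computed by exact enumeration
via `scipy.stats.fisher_exact`; any zero margin yields p = 1 by
convention.  The test suite verifies the implementation against an
independent brute-force enumerator for every 2×2 table with total ≤ 40.
No continuity corrections are applied anywhere.

Univariate odds ratios are cross-products with Wald 95 % intervals,
`exp(log OR ± 1.96·√(1/a + 1/b + 1/c + 1/d))`.  A zero cell raises by
default; the Haldane–Anscombe +0.5 correction is available behind a flag.
Wald (rather than profile-likelihood) intervals are used because they
reproduce the published intervals exactly from the printed counts.

## Multivariable logistic model

The complete-case model of the invasive label regresses on the gain
category (reference: no gains), age group (reference 50–64), race
collapsed to NH white / NH Asian-Pacific Islander / other (reference
other), hormone-receptor status (reference ER/PR positive), grade
(reference 1) and HER2 gain (reference no).  Fitting is plain maximum
likelihood via IRLS: convergence when the maximum absolute coefficient
change falls below 1e-8, at most 100 iterations; the covariance is the
inverse observed information at the optimum.  Quasi-complete separation is
flagged (`converged=False`) when any coefficient exceeds 30 on the
log-odds scale.  A rank-deficient design raises an error naming the
collinear columns.  The per-iteration log-likelihood path is retained and
is nondecreasing (a property test asserts this).

The published multivariable odds ratios themselves (9.07 for two of three
gains, 17.96 for all three) are **not** reproducible from summary counts —
they require the raw patient-level covariates — and are therefore covered
only by synthetic parameter recovery: cohorts generated with known
category log-odds are refitted end-to-end (cells → calls → categories →
model) and the Wald intervals achieve nominal ~95 % coverage over 200
replicates.  The multiple-imputation analysis of the original study is
out of scope and not implemented.

## Predictor simulation

Feature classes combine a control-arm frequency (LF 5 %, MF 15 %, HF
30 %) with a case/control fold (ND 1.0, LD 1.25, MD 1.5, HD 3.0); the
case-arm frequency is fold × control frequency capped at 1 (the fold is
anchored on controls).  The default roster has 22 features — 10 LF, 6 MF,
6 HF — with exactly one differential feature in each frequency × {LD, MD,
HD} cell and the rest nondifferential; arm sizes are 151 cases and 129
controls, matching the assayed sample set.

Each iteration draws an independent Bernoulli matrix, then fits
L1-regularized logistic regression over a path of 50 λ values log-spaced
from λ_max (the smallest λ with an all-zero slope vector, computed from
the data as max_j |x_jᵀ(y − ȳ)|/n) down to λ_max/1000.  λ is selected by
tenfold cross-validation, stratified by label with seeded shuffling:
the default rule maximizes the mean across folds of held-out AUC (ties go
to the larger λ); a minimum-mean-deviance rule is flag-selectable
(`lambda_rule="deviance"`).  The reported held-out AUC pools the
out-of-fold linear predictors at the selected λ; the active set is the
support of a full-data refit at that λ.  A class counts as selected in an
iteration when any of its features is active.

The solver minimizes `(1/n)·Σ log(1+e^η) − yη + λ‖β‖₁` with an
unpenalized intercept by outer IRLS quadratic approximation (weights
clipped below at 1e-6) and inner cyclic coordinate descent with
soft-thresholding, warm-started along the path; convergence at maximum
coefficient change < 1e-6.  It is verified against a brute-force
penalized-likelihood grid search (agreement to 1e-4) and against
scikit-learn's saga solver (agreement to ~1e-6; liblinear is not a valid
oracle because it penalizes the intercept).

At 500 iterations with a fixed seed, the moderate/high-frequency highly
differential classes are active in ≥ 99 % of iterations and the
low-frequency highly differential class in roughly two-thirds of them;
selection is monotone in fold at fixed frequency and in frequency at the
high fold.  Monte-Carlo error on a proportion near 0.65 at 500 iterations
is about ±2 points; the problem sizes here (500 iterations rather than
2000) keep a full run in a few minutes on one CPU without changing any
conclusion.

One caveat found empirically: under an all-nondifferential null the
per-feature selection rate still rises with base frequency (~0.33 LF,
~0.45 MF, ~0.52 HF per feature), because higher-variance features produce
larger spurious score correlations.  Class selection rates are therefore
not comparable *across* frequency classes under the null; the test suite
asserts exchangeability of features *within* a class and a null AUC
centred at 0.5 instead.

## Synthetic cohort generator

Latent per-sample-locus states generate the raw data: disomy (mean 2 test
copies), low gain (3.5 — one to two extra copies), high gain (6),
deletion (1), heterogeneous gain (a subclone at mean 5 in a configurable
fraction of cells, default 0.6, the rest disomic) and assay failure
(no scorable cells).  Per-cell counts are Poisson around the state mean —
the simplest integer-count model that exercises every scoring branch —
with optional binomial dropout thinning every channel; control probes are
independent with mean 2.  A deterministic noise mode reproduces rounded
true copy numbers exactly, which the tests use to separate rule logic
from sampling noise.  Scored cells per sample are uniform on 40–100.

Default state frequencies per group and locus are derived from the
published prevalence counts (gained samples split between low and high
gain using the reported low-gain shares: 80 % at 1q, 78 % at 8q24, 53 %
at 11q13; HER2 unreported, taken as 1q-like).  Covariates are sampled
independently from the published cohort marginals with missingness rates
matching the printed missing counts, so roughly 56 % of samples survive
the joint evaluability-plus-complete-case filter.  In `logistic_link`
mode, states come from the control-arm distribution for every sample and
the case label is Bernoulli with logit = log(n_cases/n_controls) + the
category's configured log-odds (defaults: logs of the published
univariate odds ratios).

What the generator does **not** model: spatial tissue structure or probe
chemistry; correlation between loci within a sample beyond what the
category link induces (real assay failures are strongly correlated across
loci — a missing core fails everywhere — so the synthetic
unable-to-determine fraction under independent failures, ~57 %, exceeds
the published 40 %); within-patient correlation for the few patients
contributing multiple samples; and covariate–genotype correlation.
Passing tests therefore establish that the pipeline's statistics are
correct under the stated sampling model, not that the scoring rules are
robust to imaging artifacts or segmentation error in real data.

## Reproducibility

Every stochastic component takes an explicit seed.  One master seed
spawns independent substreams (states, cells, labels, covariates in the
generator; one child stream per iteration in the simulation), so results
are reproducible and insensitive to execution order.
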