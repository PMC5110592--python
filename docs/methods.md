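# Methods

`aqstruct` implements a latent-structure analysis pipeline for the 50-item
adult Autism Spectrum Quotient (AQ): is the construct the questionnaire
measures a continuum of trait severity, or does it contain one or more
discrete latent classes?  Because the questionnaire data such analyses are
run on are rarely public, the package pairs every analysis stage with a
synthetic-data generator whose latent structure is known exactly, so that
each method's decision behavior can be validated against ground truth.

## Scoring model

Raw responses are on a 4-point agreement scale; each item scores 1 when the
response falls on its keyed side (agree-keyed items on "definitely/slightly
agree", disagree-keyed on the disagree side), and the total is the count of
endorsed items (0–50).  The keying table ships as an editable YAML resource
holding the instrument's standard key: the key is instrument convention,
not something estimable from data, so it is isolated as data rather than
hard-coded.  Conventional cutoffs are 26 (clinical screening) and 32
(non-clinical samples); the putative taxon used for indicator validation is
`total >= cutoff`.

Missing cells are imputed after dichotomization.  Cases missing more than a
configurable ceiling of items (default 13) are dropped and reported; items
missing in more than 2.5% of cases violate a precondition and raise.  The
default imputation is the deterministic per-item mode (ties go to 0); a
seeded Bernoulli draw from the observed item mean is available where
stochastic imputation is preferred.  Deterministic mode was chosen as the
default because it makes the whole pipeline reproducible without a seed.

Distributional descriptives use the moment estimator g1 for skewness and
excess kurtosis (b2 − 3), with a Shapiro–Wilk normality test; these
conventions are stated because published values are often quoted without
formulas.

## Composite indicators

Taxometric procedures need a few quasi-continuous indicators that separate
taxon from complement strongly (Cohen's d > 1.25), show little nuisance
covariance (mean within-group |r| < 0.3 in both groups), and come from an
adequate sample (n ≥ 300, base rate ≥ 0.05).  Indicators are composites of
dichotomized items:

* **EFA** — iterated-communality principal-axis factoring of the Pearson
  (phi) correlation matrix, squared multiple correlations as starting
  communalities, Heywood cases clamped with a warning, varimax rotation
  with Kaiser normalization.  The solution is deterministic; factor signs
  are fixed so each factor's dominant item loads positively.  Pearson
  rather than tetrachoric correlations keep every quantity an ordinary
  product-moment statistic with a simple oracle; this matches common
  practice for this instrument.
* **Retention** — parallel analysis (leading run of observed eigenvalues
  above the 95th percentile of eigenvalues from matched-shape standard
  normal data; the mean-eigenvalue reference is available but over-factors
  pure noise roughly a quarter of the time, so the percentile rule is the
  default), Velicer's MAP, Kaiser's eigenvalue-above-1 rule, and BIC over
  maximum-likelihood factor models.
* **Composites** — items are assigned to the factor with their largest
  absolute loading when it exceeds 0.2 (the tie-break rule has to be chosen;
  largest-|loading| is the least surprising), factors are merged per a
  user-supplied plan, and the composite is the sum of positively loading
  items minus negatively loading ones (for the AQ's standard four-indicator
  layout, item 30 is subtracted from indicator 2).  A packaged
  item-to-composite YAML map provides a default four-indicator layout
  covering 43 of the 50 items; it is best-effort editable data, not a
  canonical constant.

## Taxometric procedures

All four procedures rank cases on an *input* indicator and compute a
statistic of the remaining *output* indicator(s) along the ranking.  Cut
and window positions are case-rank based, making curves invariant to
monotone input transforms.  Integer composites tie heavily; ties are broken
by seeded random jitter and curves averaged over `tie_reps` (default 10)
re-orderings.

* **MAMBAC**: mean(output above cut) − mean(output below cut) at 50 evenly
  spaced cuts starting 25 cases from each extreme; K indicators give
  K(K−1) curves.
* **MAXCOV**: covariance of two outputs inside 25 windows overlapping by
  0.9 (window width `round(n / (1 + 24·0.1))`; 335 cases at n = 1139);
  K·C(K−1, 2) curves.
* **MAXEIG**: largest eigenvalue of the zero-diagonal covariance matrix of
  all outputs in the same windows; one curve per input.
* **L-Mode**: Gaussian kernel density (Silverman bandwidth, fixed grid
  [−4, 4]) of standardized Bartlett factor scores from a one-factor
  principal-axis solution of the indicator correlations.

### Base-rate estimation

Curves are smoothed with a centered 3-point moving average first; endpoint
and peak estimators are noise-sensitive.

* MAMBAC uses the endpoint estimator `p = y_left / (y_left + y_right)`:
  with complement mean 0 and taxon mean Δ on the output, the bottom-extreme
  cut gives mean-above ≈ pΔ and the top-extreme cut gives Δ(1 − p).  This
  estimator is biased upward in the presence of nuisance covariance, which
  reproduces the familiar pattern of MAMBAC base rates exceeding
  MAXCOV/MAXEIG ones.
* MAXCOV/MAXEIG use the hitmax-cut classification: the window statistic is
  proportional to p_t(1 − p_t) under the general two-class covariance
  mixture, so the maximizing window marks the input value where cases are
  half taxon; at that cut the taxon members below balance the complement
  members above, and the base rate is the fraction of cases ranked above
  the hitmax window's center.  (Averaging per-window quadratic solutions
  was evaluated and rejected: overlapping windows underweight the taxon
  tail and bias the estimate down by about a third at prevalence 0.15.)
* L-Mode reports two quantities.  The curve-level estimate is the density
  mass above the antimode between the two detected modes, with base rate 0
  and a non-taxonic flag when no credible second mode exists (a mode must
  exceed 1.05× the antimode density).  The headline estimate fits a
  two-component equal-variance Gaussian mixture to the factor scores and
  reports the upper component's weight: the component means are the latent
  modes, so this is the mode-location estimator in a form that remains
  well-defined when separation is too weak for the density to show a
  second peak — which is exactly the regime of moderately separated taxa
  (at d = 2 the factor-score mixture density is analytically unimodal).

## Comparison curves and the CCFI

Observed curves are judged against B = 100 bootstrapped replicates with
idealized categorical structure and 100 with idealized dimensional
structure, each matched to the observed data's marginals and correlations:

* Each replicate column is a bootstrap draw from the corresponding observed
  column, re-ordered along correlated normal scores; the intermediate
  correlation matrix is nudged by the residual between achieved and target
  correlations until the replicate matches the target within a mean
  absolute error of 0.01 (at most 100 iterations; the loop stops early
  once bootstrap discreteness prevents further improvement, returning the
  best replicate achieved).
* Dimensional replicates target the full-sample correlation matrix as one
  population.  Categorical replicates split cases at the base-rate cut on
  the total score (the top `round(n·base_rate)` cases form the taxon) and
  match each group's own marginals and within-group correlations
  (`idealized_within_group_r="zero"` forces within-group independence
  instead).

The identical procedure, with identical parameters and tie-break seed, is
run on the observed data and every replicate, so all curves share one
x-grid.  The fit of an ensemble is the root-mean-square deviation of the
observed panel from the ensemble pointwise mean, pooled over every curve
and x position, and

    CCFI = fit_dim / (fit_cat + fit_dim)

with > 0.6 read as categorical, < 0.4 as dimensional, and the interval
between as ambiguous.  The RMS-to-ensemble-mean fit and the ratio form are
the package's choices; they satisfy the index's published range and
threshold semantics (0–1, 0.5 symmetric, role-swap antisymmetric,
scale-invariant).

## Latent class and latent profile models

LCA models the 50 binary items as class-conditional independent Bernoulli
draws; LPA models the four composites as diagonal Gaussians with variances
shared across classes by default (the common default of the mixture
software this kind of analysis is usually run in), optionally free per
class.  Both are fitted by EM with `n_starts` random initializations
(Dirichlet weights; uniform item probabilities / resampled case means); the
first start is k-means-informed, which stabilizes recovery of
well-separated profiles at small start counts.  Endorsement probabilities
are clamped to [1e-4, 1 − 1e-4] and profile variances floored at 1e-4
(collapse to the floor is flagged as degenerate).  Classes are always
relabeled in increasing order of expected total score so class numbers are
comparable across runs, seeds and model families.

Model selection: AIC, BIC (the index this literature weights most heavily
for class enumeration), SSABIC (`ln((n+2)/24)` in place of `ln n`),
relative entropy `1 − Σ(−p log p)/(n log K)`, and the parametric
bootstrapped likelihood-ratio test with the add-one p-value rule.  The
BLRT's internal refits default to a coarser EM tolerance (1e-4) than a
final model fit: only the LRT reference distribution is needed, and the
boundary-parameter geometry makes over-parameterized null fits converge
slowly.  Lo–Mendell–Rubin and Vuong-LMR tests are deliberately not
implemented (their reference-distribution derivation is out of scope); the
stub raises `NotImplementedError`.

Local independence is screened through bivariate residuals: for every item
pair, observed vs model-expected 2×2 cell counts with residuals
`(O − E)/sqrt(E)`.  Because expectations come from fitted parameters these
residuals are conservative relative to unit normal; they are a screening
device, not a calibrated test.  Post-hoc class structure is summarized by
modal-assignment shares and per-class total-score moments, and a
multinomial logit of modal class on a binary covariate (e.g. gender)
provides per-class log-odds with Wald tests, McFadden's R² and a
likelihood-ratio G².  LCA/LPA correspondence uses a matched-class
cross-tabulation (greedy maximal-overlap matching by default, optimal
assignment available); per-class agreement divides the matched cell by the
row class size.

## Synthetic data

Three generating processes, all bit-reproducible from a seed and row-stable
under sample enlargement (independent sub-streams per random source):

* **Taxonic items/indicators** — a two-class mixture with taxon prevalence
  0.15 by default.  Indicator data are two equicorrelated
  multivariate-normal classes (within-class r = 0.2, a value comfortably
  inside the < 0.3 validity region) separated by d = 2.0 pooled-SD units on
  each of four indicators, then rounded and clamped to the feasible integer
  ranges of AQ-style composites ((0,18), (−1,8), (0,7), (0,6)).  The latent
  SD is shrunk by the 1/12 rounding variance so the realized d survives
  discretization.
* **Dimensional items/indicators** — items follow a one-factor probit
  model (standard-normal trait, threshold link), chosen because its
  pairwise endorsement probabilities have an exact bivariate-normal
  orthant oracle; indicator data are a single Gaussian population whose
  mean and covariance equal the taxonic mixture's full-sample moments
  (within-class covariance plus the rank-one between-class term), making
  the two variants moment-matched.
* **Six-class items** — a mixture of Bernoulli profiles over 50 items
  whose weights (14.7/13.9/24.6/21.1/10.5/15.4%) and expected total scores
  (24.9/23.4/15.7/11.5/24.4/37.9) emulate the severity-class structure
  reported for large non-clinical AQ samples: one high-severity class
  endorsing most items, three intermediate classes that differ in *which*
  indicator's items they endorse, and two low-severity classes, one of
  them systemising-leaning.  Per-class item probabilities were built from
  qualitative block levels over the four indicator item-sets plus mild
  within-block heterogeneity, then logit-shifted so each class's expected
  total matches its target exactly; they ship as a YAML resource and are
  an emulation, not published item-level parameters.  A per-class male
  probability supports simulating a gender covariate for the regression
  stage; gender affects nothing else (no DIF or response-style modeling).

What passing tests on these data do **not** show: real AQ items violate
local independence within classes, show item-specific wording and
response-style effects, and have missingness that is not completely at
random; none of these are modeled.  Decision-level conclusions (CCFI
discrimination, class enumeration bands) transfer to real data only to the
extent that those violations are mild.

## Problem sizes and numerical choices

The packaged analyses run at the study scale: n = 1139 cases, four
indicators, B = 100 comparison replicates per structure, K = 1..9 mixture
models.  The test suite uses n = 5000 for mixture recovery (3 starts with a
k-means first start), 50 simulations × 50 bootstrap replicates at n = 300
with 8 items for BLRT calibration, and 10 seeds for base-rate medians —
sizes chosen so each check is statistically decisive at a few minutes of
compute.  Tolerances follow from the estimators: binomial/Monte-Carlo
bounds for simulated fractions, 1e-8 for likelihood identities, 1e-10 for
vectorization-vs-naive equivalences.

Known limitations: the MAXCOV/MAXEIG base-rate resolution is bounded by the
window grid (about ±0.02 at 25 windows); the CCFI has no small-sample
correction; the BLRT is conservative near the boundary; EFA on phi
correlations attenuates loadings for extreme-prevalence items; and the
packaged six-class profiles are calibrated to class-level targets only, so
item-level comparisons against any real dataset are qualitative.
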