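# Methods

This note documents the models, algorithms and numerical choices behind
`emonet`, and what its synthetic benchmarks do and do not establish.

## The model

Observed diary series are modelled, after preprocessing, as a lag-1 vector
autoregression with correlated Gaussian innovations:

x_t = x_{t−1} A + ε_t,  ε_t ~ N(0, Σ),  Ω = Σ⁻¹.

Two networks follow. The temporal network is the directed graph of nonzero
entries of A, with a_{jk} the effect of item j at the previous beep on item
k at the current beep (diagonal = autoregression). The contemporaneous
network is the undirected graph of nonzero off-diagonal precision entries,
reported as partial correlations ρ_{jk} = −ω_{jk}/√(ω_{jj} ω_{kk}). With 14
items a saturated model has 196 lagged coefficients plus 105 free covariance
parameters, far more than ~90 beeps per person support, which is why both
matrices are estimated under L1 penalties (a time-series chain graphical
model): most entries are shrunk to exact zero and the surviving edges define
sparse, interpretable networks even for single subjects.

Population-level fits pool within-subject transitions across the subjects of
a group — a constant-coefficient model that assumes identical dynamics
within the group. Per-individual fits use one subject's transitions
(penalization keeps them feasible at p = 14, T ≈ 90; a floor of 20
transitions is enforced). Transitions never span two subjects, and the
`drop_overnight` option excludes pairs whose current observation is the
first beep of a day, treating the long evening→morning gap as missing.

## Estimation

The fit minimizes the penalized negative log-likelihood

−log det Ω + tr(S_A Ω) + λ_Ω Σ_{j≠k} |ω_{jk}| + 2 λ_A Σ_{j,k} |a_{jk}|,
S_A = (Y − X A)ᵀ(Y − X A)/n,

by alternating two convex subproblems until the relative objective change
falls below `tol` (default 1e−5, max 100 iterations):

* **Ω-step**: graphical lasso on S_A with penalty λ_Ω on off-diagonals only
  (delegated to scikit-learn's `graphical_lasso`, whose objective is exactly
  this subproblem; dual-gap tolerance `omega_tol`, default 1e−5). At
  λ_Ω = 0 the step is the closed-form inverse of S_A.
* **A-step**: cyclic coordinate descent with soft-thresholding on the
  Ω-weighted least-squares lasso, implemented on Gram matrices so the cost
  per coordinate is O(p²) regardless of n. Row-major sweep order; after each
  full sweep the iteration cycles on the active (nonzero) set until the
  largest coefficient change falls below 1e−6. At λ_A = 0 the minimizer is
  plain multivariate OLS and is solved directly.

Initialization is deterministic: A = 0, Ω = diag(1/var). Each alternating
cycle solves its subproblem at least as well as the previous iterate, so the
recorded objective path is non-increasing; if an inexactly solved subproblem
ever fails to improve the objective, the previous iterate is kept and
iteration stops. Correctness is tested two independent ways: at zero penalty
the fit must match closed-form OLS plus inverse residual covariance to 1e−6,
and at nonzero penalties the p = 2 solution must match a multi-start Powell
minimization of the identical objective to 1e−3.

Default penalties are λ_A = 0.38, λ_Ω = 0.05, the values used in the
population analyses this pipeline follows. They are scale- and data-specific
(on the package's synthetic cohorts λ_A = 0.38 empties the networks
entirely); the package therefore also implements the selection procedure
itself: a circular block bootstrap of the within-subject transition
sequences (block length ⌈√n⌉, never crossing subjects), choosing per
resample the BIC-minimizing λ_A from a candidate grid, and reporting the
median choice (inside the interquartile range by construction). BIC counts
nonzero entries of A, the upper triangle of Ω, and the p diagonal variances.
The acceptance script uses this selector rather than the fixed 0.38 for
exactly that scale reason.

Which of the two printed penalties attaches to which matrix is an
interpretation: here λ₁ (the bootstrapped one) penalizes the temporal matrix
A and λ₂ = 0.05 the precision off-diagonals. The penalty family is plain L1
(no SCAD), keeping every subproblem convex and testable.

## Preprocessing

Order is fixed: impute → detrend → quantile-transform (→ center).

* **Multiple imputation** (default 10 draws): chained equations with
  Bayesian-ridge posterior draws (scikit-learn `IterativeImputer`,
  `sample_posterior=True`, 5 rounds). Each item conditions on the other
  items at the same beep and on the within-subject lag and lead of every
  item, by augmenting the imputation matrix with shifted copies. Observed
  cells are returned bit-for-bit unchanged. All analyses run per completed
  dataset and are averaged. A subject-item series that is entirely missing,
  or a subject more than half missing, is a hard error with a per-subject
  diagnostic.
* **Detrending**: a cubic smoothing spline with fixed effective degrees of
  freedom (trace of the smoother matrix), default df = 2, is subtracted per
  subject-item series. The spline is computed in the Reinsch/Green–Silverman
  band form f = y − λQ(R + λQᵀQ)⁻¹Qᵀy, which stays numerically stable in the
  large-λ (linear-fit) limit that df = 2 lives at; λ is solved by bisection
  on log λ to |df(λ) − df| ≤ 1e−3 and cached per series length. A linear or
  constant series is reproduced exactly (zero residual), and the residual
  always has mean ~0. Detrending is always per subject; "group-wise"
  preprocessing refers only to the transformation below (per-subject splines
  with pooled residuals).
* **Normal quantile transformation**: values are replaced by
  Φ⁻¹(r/(n+1)) of their ranks (Weibull plotting position; average ranks for
  ties, so an all-tied series maps to zeros and outputs are always finite).
  At the group-wise level all subjects of a group pool into one marginal per
  item, preserving between-person level differences on the normal scale; at
  the per-individual level each subject-item series is transformed on its
  own ranks, removing them. This switch is exactly the preprocessing
  sensitivity the package's acceptance suite probes.
* **Person-mean centering** subtracts each subject's item means; it is the
  comparator literature's preprocessing and is kept separate from the
  transformation.

## Multilevel comparator

For each target item, a linear mixed model regresses the item at t on all p
lagged items, with a subject random intercept and p independent random
slopes (diagonal covariance — an unstructured 15×15 random-effect covariance
does not estimate at p = 14). Models are fitted by maximum likelihood in
statsmodels (`MixedLM`); because variance parameters often sit on the zero
boundary, an optimizer cascade (lbfgs → powell → bfgs) keeps the best finite
solution, and a target whose slopes defeat all optimizers is refitted with
the random intercept only and flagged. An edge j→k is drawn when the fixed
effect is significant at α = 0.05 (two-sided Wald with the normal
approximation — deterministic, and at ~2400 rows per model indistinguishable
from a Satterthwaite correction; no multiplicity correction, matching the
comparator's convention). The need for a time trend is decided by the
across-item average BIC of models with and without a fixed linear trend
(trend time scaled to [0,1] per subject for conditioning; ties favour "no
trend").

## Network statistics

In-strength of node k is Σ_{j≠k} |W_{jk}|, out-strength of j is
Σ_{k≠j} |W_{jk}| — self-loops excluded, which makes the mean in-strength
identically equal to the mean out-strength within a network. Four densities
are reported: edge count excluding self-loops over V(V−1); edge count
including self-loops over V² (the denominator for the including-AR variant
is a documented choice — all ordered pairs); mean |weight| over remaining
(nonzero) edges; and mean |weight| over all V² entries. "Nonzero" means
exactly nonzero: the sparse fit produces exact zeros, and multilevel
adjacencies are significance-thresholded upstream. For tabular density grids the
multilevel "average" density uses all fixed effects including
non-significant ones and includes the diagonal.

## Group inference

The Monte Carlo permutation test reshuffles subjects (never beeps) into two
pseudo-groups of the original sizes, refits both group networks with the
identical penalties, and records the density difference; the observed
difference is then located in the null as lower/upper tail proportions. Two
design points matter. First, when preprocessing is group-wise, the pooled
quantile transformation is *recomputed inside every permutation* — the
preprocessing level is part of the pipeline being tested, and freezing it
(available as a labelled fast mode) is not the faithful procedure. Second,
reshuffling is free within group sizes; the original pair-matching is not
preserved, following the description of the reshuffling as a plain
two-group reassignment. With multiple imputations the same permutation
stream runs in every completed dataset and tail proportions are averaged
(averaging proportions, not pooling draws — a documented reading of
"results were averaged"). Both tails are always reported; the headline
p-value is the lower tail of (MDD − control).

Per-subject densities from individual fits are related to baseline
covariates by univariate OLS: group and neuroticism and mean NA pooled,
severity per group (severity also defines the groups, so pooled regression
on it would be design-confounded). A constant predictor in a subgroup skips
that regression with a warning; exactly equal densities return a zero slope
with p = 1 rather than 0/0.

## Synthetic cohorts

The generator produces the study design the estimators assume: per subject a
latent stationary VAR(1) (shared sparse A plus optional Gaussian
perturbations of its nonzero entries, rejected and redrawn up to 100 times
if non-stationary; shared sparse tridiagonal precision), a slow half-period
sinusoidal trend, group- and subject-level latent offsets, discretization
through per-item cutpoints to a 1–7 scale, and MCAR missingness (default
7.5%). 100 burn-in steps are discarded. Every subject draws from an
independently spawned child of the root seed, so cohorts are reproducible
subject-by-subject.

The default two-group cohort (27 + 27 subjects, 14 items, 30 days × 3
beeps) encodes the qualitative structure of a depressed-vs-healthy diary
study: NA items shifted +1.2 latent SD in the depressed-like group, PA items
+0.8 in the healthy-like group; NA cutpoints placed high so the healthy-like
group piles up at the Likert floor; between-person baseline SD 1.0
(depressed-like) vs 0.5 (healthy-like), half of it a shared "trait affect"
component that raises NA and lowers PA together. The SDs follow the
intraclass correlations typical of diary affect items (~0.2–0.45 here);
the shared-trait structure reflects that people high in negative affect are
high across NA items, not item by item. Dynamics heterogeneity default is
hetero_sd = 0.05 on the true edges. An optional distinct overnight
transition matrix exists as a hook but has no default distinct value.

What the generator deliberately does not emulate: ordinal measurement error
beyond thresholding, missingness that depends on mood (MAR/MNAR),
time-varying dynamics within person, and any quantitative matching of the
original study's item means. Passing tests therefore show that the
estimators recover the model class they assume under realistic design,
skew, heterogeneity and missingness — not that any specific published
number is reproduced (the original raw data are not publicly deposited).

## Problem sizes and numerics of the shipped benchmarks

The test suite and the acceptance script use desk-scale sizes chosen to keep
a laptop run comfortable: 3 imputations (10 is the analysis default), 300
permutation draws (the full analysis uses 30,000), 50 bootstrap resamples
for penalty selection, 10–20 replicate seeds for recovery and calibration
experiments, and a graphical-lasso dual gap of 1e−4 in the resampling-heavy
stages (verified to leave recovered edge sets unchanged on the cohort
scale; the library default stays at 1e−5, and the oracle-equivalence tests
run at 1e−7). The permutation calibration experiment uses p = 4 with 8 + 8
subjects under an exchangeable spec; the type-I binomial bands are computed
from the nominal 5% level at test time.

## Known limitations

* Constant-coefficient pooling is exactly the assumption the individual-level
  heterogeneity in real data (and in the generator's hetero_sd > 0 cohorts)
  violates; the package reports both levels side by side rather than
  resolving the tension.
* Only lag 1 is implemented; no SCAD penalty; no structural-VAR/uSEM
  contemporaneous directionality.
* Likert data are treated as continuous after the quantile transformation;
  heavy ties at the floor make the transformed marginal only approximately
  normal.
* Wald normal-approximation p-values in the multilevel comparator are
  slightly anticonservative in small samples (visible but within binomial
  bands in the shipped calibration test).
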