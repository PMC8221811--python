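# Methods

`dacuity` reimplements, end to end and on synthetic data with known ground
truth, an analysis pipeline for a developmental cognitive-neuroscience
question: is there a single common factor behind performance across a broad
battery of decision-making tasks ("decision acuity", written *d*), is it
stable within people over time, and does resting-state functional
connectivity (rsFC) carry information about it that is distinct from IQ?

The package has two halves: a **synthetic cohort generator** that produces
data with exactly the statistical structure the analysis assumes, and the
**analysis pipeline** itself (preprocessing, factor derivation, trust-game
metrics, brain-network modules, sparse-PLS prediction with permutation
inference, and mixed-model associations). Because the generator's latent
variables and planted parameters are recorded, every stage of the pipeline is
testable as a parameter-recovery problem.

## Synthetic cohort

**Behavioral battery.** Each subject has a latent decision acuity
`d = beta_age * z(age) + b_m * z(matrix IQ) + b_v * z(vocab IQ) + residual`,
standardized to unit variance, with `beta_age = 0.24` (SD per age-SD) and IQ
slopes `(0.20, 0.35)`; the residual splits into a stable trait and an
occasion-specific part so that the latent baseline/follow-up correlation
equals `retest_r` (default 0.75). The 32 battery measures follow a linear
factor model: one signed, sparse common-loading vector (salient |loadings|
0.24–0.60; decision-noise-like parameters negative, learning rates, outcome
sensitivities and initial trust positive) plus three single-task factors
(economic preferences, information gathering, discounting) with loadings
0.40–0.60, and uniqueness absorbing the rest — so most measures keep high
uniqueness, as a heterogeneous battery does. Within each task that carries a
specific factor, the common loadings are chosen orthogonal to the specific
loading vector: the two constructs are geometrically distinct, which is what
lets an unrotated common factor be identified at all. A fixed subset of
measures (reaction times, decision-noise parameters, discounting constants —
the classically log-normal ones) is exponentiated after generation so the
gaussianization step downstream has real work; cells go missing completely at
random (default 2%, "a small percentage").

**Design.** 830 subjects in five 2-year age bins spanning 14–24 years
(uniform within bins), balanced sex, three sites; 70% retention with a
follow-up 18 ± 6 months later. Ages at follow-up are standardized by the
*baseline* mean and SD, so the age slope keeps its units. IQ subscores are
generated independent of age; the real cohort had an age–IQ dependence, but
decoupling them gives the generating age slope a single unambiguous value
for recovery tests. There is no separate wave (practice) effect by default:
within- and between-subject age slopes are equal by construction, which is
exactly what the mixed model's decomposed-age equality test should then not
reject.

**Connectivity.** Matrices are `n_nodes x n_nodes` (default 168, with 70
used in the desk-scale analyses; always 14 planted modules), built as a
block template (within-module mean 0.25, between 0.02) plus i.i.d. subject
noise (SD 0.25) per edge, plus a sparse linear signal `effect * z(score)` on
a small planted edge set per phenotype (default 10 edges inside the union of
two adjacent modules; modules 3–4 for *d*, 5–6 for IQ), plus additive
confounds on **all** edges: site offsets (±0.01), and linear head-motion
(FD) and brain-volume terms (0.03 and 0.015 per SD). The per-edge slope is
calibrated so the planted edges jointly predict the phenotype with total
R² = 0.30: because the confounds load identically on every edge they cannot
be averaged away within the planted set, so they enter the calibration —
`R² = e² / (e² + var_confound + noise²/n_edges)`. Mean FD is drawn so a
realistic minority of subjects exceed the 0.3 mm exclusion threshold.

**Trust exchanges.** The 10-round investor–trustee game is simulated under
named policies: *coaxing* (the investor escalates while the trustee returns
a near-constant fraction; fractional-change vectors point along the positive
investor axis, orientation ≈ 0°), *mutual reduction* (both fractional
contributions fall in lockstep; orientation ≈ −135° = −3π/4), and *random*.
These reproduce the two orientation poles the cooperativeness score is
anchored to.

**What the generator does not emulate.** Measure-level retest reliabilities
(stability is planted at the latent level only); non-random attrition;
age–IQ confounding; nonlinear or heteroscedastic edge effects; spatial
autocorrelation between edges sharing a node; and scanner effects richer
than additive offsets. Passing tests therefore certify the *machinery* —
estimation, inference, calibration, leak-freedom — under the model's own
assumptions, not the robustness of the method to real rsFC data.

## Preprocessing

Each measure gets the transform minimizing absolute sample skewness among
{identity, shifted log, signed power with exponent 1/3, 1/2 or 2}. The log
shift is 0 for strictly positive measures and `min − 1e-6·range` otherwise
(an always-on shift would send the sample minimum to log(ε) and wreck the
left tail). Identity is kept whenever the raw skewness is already below 0.3,
or within 0.05 of the best candidate — near-normal columns are not touched.
Missing cells are filled by iterative truncated-SVD completion on the
z-scored matrix, with the rank chosen by masking 10% of observed cells and
minimizing reconstruction RMSE (ties to the smaller rank); observed cells
are never altered. The fitted `TransformSpec` stores each measure's
transform and baseline mean/SD; follow-up tables are passed through the
*baseline* transforms and z-scored with the *baseline* moments, never their
own, so absolute change remains interpretable. The discovery/testing split
is a random half split of subjects (sizes differ by at most one). Aggregate
task performance is the mean of within-task t-scores (mean 50, SD 10) of
winnings in the four tasks with comparable earnings; the IQ composite is the
mean of the two z-scored raw subscores.

## Factor pipeline

Parallel analysis (95th percentile of eigenvalues from size-matched
standard-normal data, leading-run counting rule) bounds the factor count.
Exploratory models are minimum-residual (minres) factor analyses: the
uniquenesses are optimized by L-BFGS-B to minimize the off-diagonal squared
residuals of the correlation matrix, with loadings from the reduced matrix's
top-k eigenstructure. **The exploratory solution is left unrotated by
default.** This is a deliberate choice: simple-structure rotations (oblimin
and relatives) are built to dissolve exactly the kind of broad,
many-measure factor that decision acuity is, redistributing its variance
into cluster factors — on data with a planted diffuse common factor,
quartimin reliably destroys it. The unrotated first principal factor, by
contrast, is the maximum-variance direction of the common space and recovers
the planted vector essentially perfectly. Oblimin (gradient-projection
algorithm) remains available via `rotation="oblimin"` for cluster-like
factor structures. Factors are ordered by explained variance and signed so
that the majority of salient (|loading| ≥ 0.25) entries are positive; all
comparisons between factor solutions go through Tucker-congruence matching
(Hungarian assignment plus sign alignment), since factor models are defined
only up to column permutation and sign.

Confirmatory models free only loadings with exploratory |loading| ≥ 0.25
(the battery's loadings are diffuse, so the conventional 0.4 would starve
the model), fix latent variances at 1, leave factor correlations free, and
are fitted to the disjoint test half by maximum likelihood with analytic
gradients. Fit is summarized by chi-square, BIC (`chi2 + q·ln n`), CFI, and
RMSEA with a 90% interval from inverting the noncentral chi-square. The
retained `k` is the largest whose fit converges and improves BIC over the
previous converging model; a factor with no freed loadings makes that `k`
under-identified and excludes it. Factor scores use Thurstone regression
weights `W = R⁻¹ Λ Φ`; longitudinal scoring zeroes the weights of measures
from the task not assessed at follow-up and uses the raw weighted sum
without renormalization (the conservative choice — scores stay on the
baseline scale). Split-half construct stability correlates, within one half,
the scores from its own loadings with scores from the other half's
congruence-matched loadings.

## Trust metrics

For rounds t ≥ 2, `dI = (I_t − I_{t−1}) / endowment` and
`dT = R_t/(3·I_t) − R_{t−1}/(3·I_{t−1})`: each party's change is measured as
a fraction of what they *could* have given. A round where the investor gave
nothing leaves the trustee fraction defined as 0 (returning money on such a
round is an invalid exchange). The (dI, dT) vector is classified by its
angle from the dI axis, quadrants closed on the upper edge, labels
retaliating → repairing → honoring → disrupting as the angle rises from
−180° to 180° (so (−0.2, −0.2), at −135°, is retaliating and the worked
example (0.25, −0.0556), at −12.5°, is repairing). Exact zero vectors are
unclassified. The vector sum of the round vectors characterizes the whole
exchange: its angle is the orientation, its length over `n_rounds − 1`
transitions the responsiveness (the per-transition normalization is our
convention; an unnormalized sum is recoverable by multiplication), and
cooperativeness is the position, clipped to [0, 1], of the unit vector at
the orientation projected onto the chord from the −135° pole (value 0) to
the 0° pole (value 1). The poles are fixed at the two printed cluster
centers rather than refit per dataset, which would make the score
sample-dependent.

## Network modules

Subjects with mean FD > 0.3 mm are excluded. The baseline matrices are
averaged and negative entries removed; the resulting weighted graph is
partitioned by Louvain community detection (igraph's multilevel
implementation, resolution γ) followed by a Kernighan–Lin-style single-node
best-move refinement until no move improves modularity. Because the
algorithm is stochastic it is run `n_runs` times (100 at full scale); runs
are gathered in a node × node co-assignment matrix, which is itself
re-partitioned (unthresholded, at γ = 1, zero diagonal) until all runs
agree — non-convergence after 20 rounds is an error. γ is tuned on a
stability plateau: for each grid value the consensus partition is computed
and scored by the mean NMI (arithmetic-mean normalization) with the
partitions at adjacent grid values; the maximizer wins and ties go to the
smaller γ. The "adjacent-resolution agreement" reading of the stability
criterion is one of two defensible readings (the other is within-γ
run-to-run agreement); it is the implemented one.

## SPLS prediction engine

Features are the vectorized edges (node pairs i < j, row-major — the fixed
order every module shares). Per component, SPLS computes the
cross-covariance `z = X'y` on the deflated matrix, admits features with
`|z| ≥ η·max|z|`, takes the normalized soft-thresholded z as the direction,
extracts the score and deflates; final coefficients are a dense PLS refit on
the union active set. At η = 0 this is exactly dense PLS regression (tested
against an independent implementation to 1e-8).

The surrounding pipeline, per outer fold: the *target* (never the features)
is residualized on age, sex, age×sex, brain volume, site indicators, mean FD
and denoising degrees of freedom, with coefficients fitted on training rows
only and applied to both partitions; features are standardized by training
statistics; features significantly correlated with the training target
(p < 0.05) pass the prefilter (applied once per training partition, not per
bootstrap resample — it is a speed step that precedes the model); an inner
cross-validated grid search over (η, K) minimizes MSE with ties broken
toward sparser models (larger η, then smaller K), using un-bagged fits; the
winning configuration is bagged over bootstrap resamples (coefficients
averaged, selection frequencies recorded; 200 resamples at full scale) and
applied to the test fold. Outer folds are stratified by target quantile and
seeded. Every subject is predicted once per repeat; the per-repeat accuracy
is the Pearson correlation between the assembled residualized target and
the predictions, and `r_mean` averages repeats. An empty prefilter yields a
training-mean predictor with a warning (its r is defined as 0).

**Permutation inference.** The residualized target is permuted across the
whole sample, the fold structure and per-fold standardization are kept, and
the full per-fold fitting (prefilter, inner search, bagging) is redone per
permutation. Null r values are Fisher-transformed; the SD of the
zero-centered Gaussian null is `sqrt(mean(z²))` and the observed Fisher-z is
referred to it one-tailed. Calibration is verified empirically: under null
data the p-values are uniform and the 5% test holds its level.

**Virtual lesions** retrain the whole pipeline on each module's edges
(intra-modular plus edges to the rest of the brain) and on all edges;
Benjamini–Hochberg FDR runs across the whole family (modules +
all-connections; 15 tests at 14 modules). **Specificity** is the partial
correlation between observed and predicted scores controlling the other
phenotype (the OLS-residual identity), with significance from the same
permutation nulls (stored null predictions and permuted targets enter the
identical partial-correlation computation). **Transfer** applies the frozen
baseline fold-models to follow-up data: each follow-up subject is predicted
by the model of the fold in which they were a baseline *test* subject, so
nobody is predicted by a model that saw their own baseline data; follow-up
targets are residualized with the baseline fold's confound coefficients.
Because the transferred models are frozen, the transfer null permutes the
residualized follow-up target against the fixed predictions.

## Mixed-effects associations

A participant random intercept handles the two-wave structure (random age
slopes are omitted by default — they worsen fit in data of this shape). Age
enters as the subject's mean age (between-subject slope) and the deviation
of each visit from it (within-subject slope); their equality is tested by a
Wald contrast. Standardized coefficients come from a refit on z-scored
variables. BIC is `−2·loglik + q·ln N`. A variance estimate on the zero
boundary triggers a warning and an OLS comparison fit (whose fixed effects
the mixed model then matches). Recovery of the generating age slope (0.24)
is verified by confidence-interval coverage across replicate cohorts, on the
generator's latent *d*: the recovery test certifies the mixed-model
machinery, not factor-score attenuation, which would shrink the slope by the
score's validity as a matter of algebra, not of estimation error.

## Problem sizes and numerical choices

The analysis drivers and the acceptance checks run at desk scale, chosen as
the package's own defaults: cohorts of 800–830 (the battery analyses), ~320
scanned subjects on 70-node / 14-module graphs with 10 planted edges per
phenotype, 20 outer folds, 1–2 repeats, η ∈ {0.7, 0.9}, K ∈ {1, 2}, 20–50
bootstrap resamples and 30–50 permutations; calibration uses 40–50 null
datasets at n ≈ 150 with 300 edges. The full-scale design constants
(20 outer / 10 inner folds, 5 repeats, 200 resamples, 100 permutations) are
the `SPLSConfig` defaults. Other numerical conventions: minres uniquenesses
bounded in [1e-3, 1]; CFA parameters bounded (loadings ±2, uniqueness
[1e-3, 1], factor correlations ±0.95) with a Cholesky feasibility guard;
modularity move tolerance 1e-12; correlation r clipped away from ±1 before
Fisher transform; permutation p floored at the smallest positive float;
degenerate (constant) vectors raise rather than silently correlate.

## Known limitations

* The unrotated-factor default is appropriate when the object of interest is
  a broad general factor; for cluster-structured batteries use oblimin.
* The permutation null refits with the first repeat's assembled residualized
  target as its base; with several repeats the observed statistic averages
  over more fold splits than each null draw, which is slightly conservative.
* The zero-centered-Gaussian null with its SD estimated from a finite number
  of permutations is an approximation: across several hundred simulated null
  datasets at the reduced calibration scale the measured 5% rejection rate
  ranged from 0.03 to 0.10 per batch (about 0.06 pooled), i.e. the test is
  close to nominal but its extreme tail can be mildly anti-conservative when
  the permutation count is small. More permutations tighten it.
* Consensus re-partitioning at γ = 1 on the co-assignment matrix is the
  standard recipe but not the only one; very flat consensus matrices can
  oscillate (bounded by the iteration cap).
* The imputation is MCAR-oriented, like the generator; it has no machinery
  for systematic missingness.
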