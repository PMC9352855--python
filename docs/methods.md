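# Methods

## Model

Each participant's p-variate ROI series is modeled as a unified SEM
(structural VAR(1) with contemporaneous effects):

    η_t = A η_t + Φ η_{t−1} + ζ_t,    ζ_t ~ N(0, Ψ),  Ψ diagonal

- `A` (p×p, zero diagonal): directed contemporaneous (same-volume)
  effects; entry (i, j) is the effect of ROI j on ROI i.
- `Φ` (p×p): directed lag-1 effects; the diagonal holds the
  autoregressive (AR) paths, which are always included and never
  pruned.
- `Ψ`: innovation variances, one per ROI, always free. Diagonal Ψ is
  the standard assumption for this model class; all dependence between
  regions must flow through A and Φ.

The reduced form is `η_t = (I−A)^{-1}(Φ η_{t−1} + ζ_t)`; a system is
admissible when `(I−A)` is invertible and stationary when the spectral
radius of `(I−A)^{-1}Φ` is below 1.

## Estimation frame

Estimation is full-information ML on the covariance of the *lagged
sample*: rows `[η_{t−1}, η_t]` pooled within runs (no pair spans a run
boundary, because runs are acquired separately and concatenated
afterwards), columns mean-centered over the pooled sample, covariance
with denominator N−1 where N = Σ_r (T_r − 1). Means are not modeled.
The 2p-block model saturates the predictor block (the covariance of
η_{t−1}); since the conditional parameters (A, Φ, Ψ) do not constrain
that block, the Gaussian likelihood factors exactly and the ML
discrepancy reduces to the conditional form

    F = ln|Ω| − ln|S22.1| + tr(Ω^{-1} M) − p
    Ω = BΨB',  G = BΦ,  B = (I−A)^{-1},
    M = S22.1 + (G − Ĝ) S11 (G − Ĝ)',

with `Ĝ = S21 S11^{-1}` and `S22.1` the conditional sample covariance.
Model chi-square is `(N−1)·F` at the minimum; the test suite verifies
the factorization against the explicit 2p-block discrepancy.

Degrees of freedom follow the 2p-block moment count: `p(2p+1)` unique
moments, minus `p(p+1)/2` absorbed by the saturated predictor block,
minus p innovation variances, minus the number of freed paths, i.e.
`df = p(2p+1) − p(p+1)/2 − p − k`. At p = 10 this is `145 − k`, so df
decreases one-for-one with network complexity.

With only lagged paths free, the ML solution coincides with
per-equation least squares of η_t on η_{t−1}; this closed-form oracle
anchors the estimation tests. A "saturated" (df = 0) comparison model
must be *just-identified*: a recursive (triangular) contemporaneous
ordering plus all lagged paths. Freeing both directions of every
contemporaneous pair would exceed the conditional moment count and
lose identification.

Fit indices: RMSEA = sqrt(max(χ²−df, 0)/(df·(N−1))) (0 at df = 0);
CFI = 1 − max(χ²_M−df_M, 0)/max(χ²_B−df_B, χ²_M−df_M, 0), clamped to
[0, 1] and exactly 1 at df = 0; NNFI = (χ²_B/df_B − χ²_M/df_M)/(χ²_B/df_B − 1),
not clamped, reported as 1 with a flag when df = 0; SRMR = root mean
square of the standardized residuals (S − Σ(θ)) over all unique
moments of the 2p block. The baseline model frees only Ψ (A = Φ = 0)
with the predictor block saturated; its solution is closed-form
(ψ_i = s22_ii, F_B = ln|diag(S22)| − ln|S22.1|).

## Optimizer

The discrepancy and its analytic gradient are compiled with numba, and
minimization uses a dense BFGS with Armijo backtracking written into
the same kernel. This is deliberate: the model search performs
thousands of warm-started one-path refits per dataset, and the
per-call overhead of a generic optimizer dominates at that scale. The
scipy L-BFGS-B route on a pure-numpy objective is kept in the package
(`_mlref`) and must agree with the kernel's minima in the tests.

Numerical choices:

- parameters: free entries of A and Φ plus log ψ (positivity by
  parameterization);
- warm start: per-equation least squares computed from the moment
  matrix; one-path refits start at the restricted solution with the
  new parameter at 0, so chi-square is monotone under nesting;
- convergence: gradient sup-norm below 1e-7, or relative F decrease
  below 1e-11 *provided* the gradient is below 1e-3 — a stall with a
  large gradient is reported as non-convergence, not convergence;
- restarts on non-convergence: a fresh least-squares start, then
  deterministic jittered perturbations of the best point (up to 3);
- inadmissible trial points — singular (I−A), non-positive-definite
  Ω, or ‖(I−A)^{-1}‖²_F > 1e10 (contemporaneous loops drifting toward
  singularity) — evaluate to +inf and are rejected by the line search;
- the Cholesky and Gauss–Jordan helpers inside the kernel are written
  longhand because np.linalg raises uncatchably in nopython mode at
  exactly the trial points the line search must survive; numpy
  verifies them in the tests.

Standard errors come from the inverse observed information
((N−1)/2 × Hessian of F, the Hessian by central differences of the
analytic gradient). Near-collinear predictors can leave an *empirically
unidentified* direction with a numerically zero information
eigenvalue; parameters loading on such a direction get SE = +inf
(z = 0), which routes them into pruning rather than aborting the fit.
A matrix singular or indefinite beyond tolerance raises a
rank-deficiency error.

## Modification indices

The score for freeing one absent path is the *realized* chi-square
drop from re-estimating with that single path freed (warm-started, so
each refit costs a fraction of a millisecond). This is the
Lagrange-multiplier search statistic without the quadratic
approximation; each score is referred to χ²(1). Candidates are all
absent paths except contemporaneous self-loops; both directions of a
pair are distinct candidates. Scores are sorted descending with ties
broken by (lag, source, target) for determinism.

## Search

- **Group criterion**: a candidate enters the group structure when its
  score is significant (α = .05, uncorrected by default; Bonferroni by
  config) for at least ⌈0.75·n⌉ participants (9 of 11 — "at least 75%"
  forces ≥, and the ceiling is the conservative integerization). Best
  candidate by participant count, then summed score, then lexicographic
  key. Participants whose fit fails at a step are excluded from counts
  (logged); if more than 25% fail the search aborts.
- **Group pruning**: group paths whose estimates are z-significant
  (α = .05 two-sided) for fewer than ⌈0.75·n⌉ participants are removed
  one at a time (least-supported first, refitting in between) to a
  fixed point. One-at-a-time removal avoids over-pruning correlated
  estimates.
- **Individual stage**: per participant, add the best significant
  candidate until ≥ 2 of the four excellent-fit cutoffs hold
  (RMSEA ≤ .05, SRMR ≤ .05, CFI ≥ .95, NNFI ≥ .95 — "fits well" is not
  defined in this literature's applications; 2-of-4 is the established
  default), no significant candidate remains, or the iteration cap is
  hit. The fit rule is checked before any addition, so a well-fitting
  group model is returned unchanged. Nonsignificant individual paths
  are then pruned (never group or AR paths). A failed refit rolls back
  the last addition and stops, flagged in the trace.
- **Confirmatory group pruning** (final stage, on by default): group
  paths are re-tested with the same 75% z-criterion inside each
  person's *completed* model. Pruning during the group stage tests
  z-values under group-only models, where a participant's still-missing
  individual paths bias marginal group-path estimates; in benchmarks
  this promoted paths truly belonging to 2–5 individuals to group
  level. Paths failing the re-check are demoted: kept at individual
  level for participants whose estimate is significant, removed
  elsewhere. Containment (every final structure contains the final
  group structure) is preserved.

Every addition, pruning, and stop is logged in a trace that replays to
the final structures; the whole search is deterministic given data and
config.

## Synthetic data generator

The generator emulates the study conditions: n = 11 participants,
p = 10 ROIs (6 MRN + 4 DMN), two independent runs of 134 volumes
(burn-in 100 steps each, discarded; runs are separate realizations
because the real runs were acquired separately and concatenated),
≈ 12 group non-AR paths, 10–15 individual paths per person, weight
magnitudes uniform in [0.3, 0.6] (AR positive; others random sign),
innovation variances uniform in [0.8, 1.2]. Path placement samples
categories (within-MRN, within-DMN, between) with weights
(.48, .24, .28), normalized by available slots per category, so the
planted density profile lands near the within-MRN-dominant pattern
typical of rotation-task data; the category weights and a 50/50
contemporaneous/lagged split were fixed once at those values. Weights
are rejection-resampled per participant until the spectral radius of
`(I−A)^{-1}Φ` is below 0.9.

Contemporaneous truth matrices are *recursive by default*: all lag-0
paths in one draw respect a hidden random ordering of the ROIs. A
contemporaneous two-cycle (or a path and its reverse) is nearly
observationally equivalent to its flip at fMRI-length series, which
makes directed recovery ill-posed rather than hard; recursive truths
keep the benchmark meaningful while the estimator still searches the
full directed candidate space. The flag `acyclic_contemporaneous`
restores unrestricted placement.

Covariates use the study-scale moments (estradiol 1.33 ± 0.71,
progesterone 239.01 ± 124.99, testosterone 132.82 ± 64.88 pg/mL;
75.00 ± 8.39 % correct) with an optional linear coupling of each
variable to the participant's standardized true individual-path count
(defaults: behavior 0.5, progesterone and testosterone 0.4, estradiol
0), so planted brain–behavior correlations exist. Draws are clipped at
zero — hormone concentrations cannot be negative, and clipping (rather
than conditional truncation) leaves the sample mean within a fraction
of a percent of the target at these mean/SD ratios; % correct is also
clipped at 100.

What the generator does **not** model: hemodynamic convolution,
scanner drift, motion, non-Gaussian innovations, higher-order lags.
Passing benchmarks therefore show the pipeline recovers truth *when
the model class is correct*; they do not certify behavior under BOLD
misspecification.

## Metrics and multimodal statistics

Complexity = number of estimated connections, AR self-loops included
(the study-scale density proportions only sum consistently if the ~10
residual connections are the AR paths, so AR counts toward complexity
but toward none of the three densities; `count_ar_in` exposes
`complexity | densities | neither`). A non-AR edge is within-MRN,
within-DMN, or between by its endpoints; lag-0 and lag-1 edges count
identically and separately. Densities divide counts by complexity; an
empty network reports densities 0 with a degenerate flag.

Correlations are Pearson by default (Spearman by flag), pairwise
complete with per-cell n recorded; zero-variance variables yield
missing cells with a warning. No significance testing is attached by
default — at n = 11 the matrix is descriptive; exploratory p-values
are available and labeled as such.

## Validation studies and problem sizes

The packaged studies (also recomputed by `scripts/acceptance.py`):

- estimation oracle at T = 10 000 (ML vs OLS; weight recovery);
- fit-index arithmetic on fixed (χ², df, N) triples;
- modification-index contract on p ≤ 4 instances against
  independent scipy refits;
- null specificity: 20 AR-only datasets at n = 11, T = 2×134;
- recovery: 10 planted study-scale datasets (12 group paths, 10–15
  individual, |β| ∈ [0.3, 0.6]);
- metric counting on an enumerated 35-connection network;
- end-to-end determinism of two identical study-scale runs.

These sizes were chosen to exercise the study-scale regime while
keeping a full validation run in minutes on one CPU.

## Known limitations

- Contemporaneous direction recovery is intrinsically weakly
  identified at ~270 volumes; the benchmark plants recursive truths,
  and on real data individual contemporaneous directions should be
  interpreted cautiously.
- The individual stage stops at "fits well", so weak true paths
  (|β| ≈ 0.3) can remain unrecovered once the fit rule is satisfied;
  edge recall ~0.84 on the benchmark reflects this, not estimator
  bias.
- Exact-refit modification indices are exact for single additions but
  the search remains greedy; it inherits GIMME's known path-dependence.
- n = 11 correlations have wide sampling variability; the multimodal
  stage is descriptive by design.
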