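# Methods

## Problem

Community screening programs that serve uninsured and undocumented
populations produce sparse laboratory reports: not every analyte is ordered
for every participant, and demographic fields are unevenly completed.  This
package treats the resulting cohort table as a matrix-completion problem.
The encoded table `X` (patients × features, all entries non-negative) is
approximated by a low-rank non-negative product `U V`; observed cells drive
the fit and the reconstruction imputes the unobserved ones.  The imputed
total-cholesterol-to-HDL ratio (CHOL/HDL) is then banded into four ordinal
cardiovascular risk levels, which is the quantity the pipeline is scored on.

## Masked factorization

The solver minimizes the masked Frobenius objective

    f(U, V) = ½ Σ_{ij: M_ij = 1} (X_ij − (UV)_ij)²,   U ≥ 0, V ≥ 0,

where `M` is the binary observation mask.  Updates are masked Lee–Seung
multiplicative rules; the U-update denominator additionally carries the
gradient `λ U (UᵀU − I)` of an orthogonality penalty `λ/2 ‖UᵀU − I‖²_F`
on the patient factors, which discourages redundant components and, at
`λ = 0`, reduces the scheme to plain masked NMF.  In that limit each
combined (U, V) update never increases the objective — the classical
multiplicative-update guarantee — and the property is numerically asserted
in the test suite (tolerance 1e−10 per step).  Denominators are floored at
`δ = 1e−12` and factors clipped at zero, so non-negativity is exact.

Convergence is declared when the *step error*, the relative objective
change `|f_t − f_{t−1}| / max(f_{t−1}, δ)`, falls below the tolerance `ε`.
Non-convergence at `max_iter` is reported through a flag, never raised:
the trace (objective and step error per iteration, optionally factor
snapshots) is always returned for inspection.

Parameters and defaults:

| parameter | default | rationale |
|---|---|---|
| rank `k` | 4 | one latent dimension per risk level; configurable |
| `ε` | 1e−5 | the tightest of the standard tolerances {1e−2 … 1e−5} |
| `max_iter` | 500 | the trajectory typically plateaus within tens of iterations |
| `λ` (ortho_weight) | 0.1 | mild penalty; `0` recovers plain masked NMF |
| init | seeded half-normal, scaled by `mean(X)/k` | NNDSVD (mean-filled variant) behind a flag |

## Encoding

Binary features encode as {1, 2} rather than {0, 1}: a structural zero in
`X` can lock a multiplicative update, and strictly positive codes avoid
that pathology.  Race encodes as consecutive positive integers; continuous
labs are min-max scaled to [0, 1] over their observed entries (z-scores
would be negative).  Unobserved cells hold the column's observed mean as a
finite placeholder — the masked objective never reads them.  The per-column
affine maps are stored so every observed cell decodes back to clinical
units to 1e−9 relative accuracy; reconstructed values that undershoot the
scaled range clip to the column's clinical floor.  The patient account
number is parsed but excluded from `X` by default (an identifier carries no
plausible signal); a flag restores it as a factorized positive integer.

## Risk bands

The four levels use the standard screening cutpoints: male CHOL/HDL
4.2 / 7.4 / 11.5, female 3.9 / 5.8 / 9.0, HDL% 25 / 15 / 9.  The printed
bands leave a gap (male ratio 7.3–7.4) and an overlap (HDL% 15); they are
resolved into contiguous half-open intervals — lower ratio cutpoints belong
to the higher-risk side, the top ratio cutpoint to the moderate band,
shared HDL% cutpoints to the lower-risk band — so that every positive input
classifies exactly once.  All conventions live in `RiskThresholds` and are
overridable.

Soft assignment is a declared functional form (the underlying study names
the method without a formula): triangular membership kernels evaluated in a
*warped category coordinate* `t(r)` that is piecewise linear with `t = j`
at band j's midpoint and `t = j + ½` at each cutpoint (outer bands use
cutpoint ∓ bandwidth as their centre; bandwidth defaults to half the
narrowest interior band width for the sex).  This construction makes the
kernels a partition of unity, splits the weight 50/50 exactly at each
cutpoint, and — unlike a plain triangular partition over the raw ratio,
whose crossovers drift off the cutpoints when band widths are unequal —
guarantees that the soft argmax agrees with the hard band everywhere off
the cutpoint set, for any bandwidth.

## Baseline

The comparison model is an L2-regularized multinomial (softmax) logistic
regression predicting the risk level from the other encoded features,
trained by full-batch gradient descent with Armijo backtracking to gradient
norm < 1e−6 (λ = 1e−3, intercept unpenalized, features standardized
internally, missing features mean-imputed).  A scikit-learn fit serves as
an independent cross-check in the tests, never as the implementation.  A
second, deliberately trivial baseline imputes every held-out ratio with the
training-column mean.

## Synthetic cohort generator

The generator emulates a 300-participant hepatitis-B screening cohort
stratified by SSN status (199 SSN−, 101 SSN+), reproducing the published
group marginals: per-group truncated-normal labs (age, fasting glucose,
CHOL, TG, CHOL/HDL, LDL, TSH), Bernoulli serology (HBsAb+ 52%/39%,
HBsAg+ 9%/8%), sex and race proportions, and PSA observed for exactly 43
participants (subset-tested missingness), none above 4.2 ng/mL.  PSA's
marginal is not published; a truncated normal with mean 1.1, SD 0.7 on
[0.02, 4.2] is used, identical in both groups — a realistic range for a
largely older male screening population under the printed ceiling.

Two deliberate modelling choices:

* **Moment matching.**  Truncating a normal at the printed min/max shifts
  its mean (by ~+20 mg/dL for the heavily right-skewed SSN+ triglycerides)
  and shrinks its SD.  The generator solves numerically for the underlying
  (μ, σ) whose truncated distribution has exactly the target mean and SD,
  so sample moments are unbiased for the printed values at any n.  The
  solve succeeds for all 14 group × variable marginals (residual < 1e−13).
* **Independence within group.**  The published tables carry no covariance
  information, so variables are drawn independently within group; the only
  dependence is structural, HDL = CHOL / ratio, which makes `chol_hdl`
  exactly CHOL/HDL by construction (ratios implying an HDL outside
  15–150 mg/dL are redrawn; this is rare and leaves the ratio marginal
  essentially intact).  An exchangeable Gaussian-copula knob exists for
  sensitivity analyses but defaults off: inventing unprinted correlations
  by default would misrepresent the population being emulated.

What passing tests on these cohorts show — and what they do not: marginal
and rate fidelity, missingness mechanics, and end-to-end pipeline behaviour
are covered; real screening data have correlated labs (age–TSH,
CHOL–LDL–TG), non-normal tails (TG is log-normal-like), and missingness
that is informative rather than MCAR, none of which the default generator
reproduces.  Accuracy figures on synthetic cohorts therefore do not
estimate accuracy on real cohorts.

A separate low-rank testbed (`generate_lowrank`) draws `X = clip(U*V* +
noise, 0)` with known factors and an MCAR mask guaranteed to keep every row
and column observed; it is the ground-truth instrument for solver
validation (noiseless reconstruction to < 1% relative error; 20% held-out
cells recovered to < 10% relative error at the true rank).

## Evaluation design

`holdout_chol_hdl` masks a seeded 20% of the observed CHOL/HDL cells
(fraction configurable) and replaces their training values with the
column placeholder so no information leaks through the matrix itself.
Accuracy is the exact-match fraction between risk levels implied by the
imputed and the true ratios, scored per held-out cell; the 4×4 confusion
matrix and, when snapshots are stored, per-iteration accuracy and mean
soft-membership trajectories accompany it.  Group summaries report Welch
*and* pooled t-tests (the convention behind published two-sample p-values
is rarely stated, so both are emitted) and two-proportion chi-square tests
with and without continuity correction.

## Known limitations

* A rank-4 uncentered factorization of a cohort whose columns are
  independent apart from the CHOL–HDL–ratio triple spends its components on
  the high-variance binary/categorical columns and captures little of the
  ratio's covariance; on such cohorts it does not reliably beat column-mean
  imputation (a rank-4 truncated SVD — the unconstrained optimum of the
  same objective — behaves identically, so this is representational, not a
  solver defect).  With genuine low-rank structure, or at higher rank, the
  factorization wins clearly; both regimes are exercised in the tests.
* The multiplicative updates converge linearly at best; ill-conditioned
  problems near a zero factor entry slow down (mitigated by the strictly
  positive encoding and the mean-filled NNDSVD variant).
* The orthogonality penalty destroys the exact monotonicity guarantee for
  `λ > 0`; in practice the trace remains monotone to high accuracy at the
  default `λ = 0.1`.
* Problem sizes in the test and acceptance runs (cohorts of 300–20,000
  rows, 30×16 to 100×16 solver instances, 20-seed replications) were chosen
  as comfortable desk-scale experiments for a single CPU.
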