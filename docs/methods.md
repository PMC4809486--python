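# Methods

## Selection as a missing-data mechanism

The package models the evaluation setting of selection procedures: an
applicant pool of size N with a continuous predictor X, a dichotomous
criterion Y (1 = successful), and — under indirect range restriction
(IRR) — a continuous selection variable Z.  Top-down selection keeps the
top `round(N·sr)` cases by X (direct restriction, DRR) or by Z (IRR) and
deletes Y for everyone else; X and Z stay observed for all applicants.
Because the missing indicator is a deterministic function of a fully
observed variable, the missingness is MAR, and the conditional
distribution of Y given the observed predictors is estimable from the
selected cases alone.

## Estimators

**Classical correction (Case 2 / Case 3).**  The restricted-sample
correlation between X and the 0/1 criterion is computed as the
point-biserial (identically the Pearson correlation with the 0/1 coding).
For an artificially dichotomous criterion — a continuous trait split at a
cut-off — that coefficient is first converted to a biserial,
`r_b = r_pb·√(pq)/h`, with `h` the standard normal ordinate at the split
and p, q the *selected sample's* proportions (the only proportions this
method can observe); the Case-2 or Case-3 formula is then applied to the
converted coefficient, using the sd ratio of the selection variable
(restricted sd from selected cases, unrestricted from all applicants) and,
for Case 3, the restricted-sample Z–X and Z–criterion correlations (the
latter biserial-converted in the artificial case, matching the design's
intercorrelation convention).  Convert-then-correct reproduces the
published accuracy results this framework replicates; correcting the
point-biserial first and converting afterwards produces a visibly
different (fading) bias profile.  The selected-sample success
proportion is a biased estimate of the base rate, which is exactly why
the corrected biserial stays biased — and the method provides no base-rate
estimate at all.

**Multiple imputation.**  A logistic regression of Y on X (DRR) or on X
and Z (IRR) — the predictor set must contain the cause of missingness for
MAR validity — is fitted to the selected cases by ridge-penalized IRLS
(ridge 1e-5, deviance-change convergence at 1e-8 relative, 25-iteration
cap).  Since Y is the only incomplete variable, the chained-equations
cycle collapses to this single conditional model.  Each of m imputations
draws a coefficient vector from the large-sample posterior — multivariate
normal at the penalized optimum with inverse-information covariance — and
fills each unselected case with a Bernoulli draw at its fitted
probability; observed values are never altered.  Per completed dataset we
compute r_pb, the success proportion (the base-rate estimate), and for the
artificial kind the biserial using *that dataset's own* completed
proportion — this is how the approach undoes the success-rate bias.
Point estimates are pooled as arithmetic means over the m imputations
(no between/within variance combination: the evaluation uses point
estimates only).

**Data augmentation.**  The logistic fit includes, by default, the
White–Daniel–Royston augmentation used by standard imputation software:
for each predictor, pseudo-observations at the full-sample mean ± 0.5 sd
with both criterion labels, carrying total weight p + 1.  This guards
against separation (realistic at SR = .1 with a strong association and an
extreme base rate) and, because the pseudo-points use all-applicant
moments, mildly shrinks extrapolated probabilities toward one half in the
unselected range.  The accuracy profile of the method at severe
restriction — the downward bias of the pooled correlation and the upward
bias of the base-rate estimate at SR = .1 — depends on this component;
without it the biases are roughly halved and the base-rate estimate is
noisier.  `multiple_impute(augment=False)` disables it.

## Synthetic applicant populations

Two data models, each for DRR and IRR:

* **Artificial dichotomy** — standard bivariate/trivariate normal with
  target correlations; Y = 1 where the latent criterion exceeds
  `c = Φ⁻¹(1 − BR)`, so the expected success proportion equals BR.
* **Natural dichotomy** — Y ~ Bernoulli(BR); within each criterion group
  X (and Z) are unit-variance normals with group mean difference d chosen
  to hit a target point-biserial via `d = √(ρ²/(pq(1−ρ²)))` (the mixture
  sd is `√(1 + pq·d²)`; d = 1.5 at BR = .5 gives σ_X = 1.25 and
  ρ_pb = .60).  For IRR the within-group X–Z correlation is solved from
  the target marginal Z–X correlation via the mixture covariance identity
  `ρ_w = ρ_ZX σ_X σ_Z − pq·d_x d_z`.

Defaults are the study conditions: N = 500, all correlations and the BR
drawn uniformly on [.1, .9], selection ratios .1–.9 in steps of .1,
m = 20 imputations.  Group membership is i.i.d. Bernoulli rather than
fixed counts, modelling a random applicant population in which the
realized base rate is itself random (`fixed_counts=True` switches to
fixed counts).  Infeasible factor draws — a non-positive-definite latent
correlation matrix, or an implied within-group correlation outside
(−1, 1) — are rejected and redrawn.

What the generators do *not* emulate: non-normal (skewed, heavy-tailed)
predictors, measurement error in X or Z, more than three variables,
probabilistic or banded selection, and self-selection (MNAR).  Passing
accuracy tests therefore demonstrate correctness of the estimators under
the normal-theory/mixture data models, not robustness to real-data
violations of them.

## Accuracy analysis

Residuals are estimate minus *unrestricted-sample* statistic (not the
population parameter): the evaluation asks how well a correction recovers
what would have been computed had nobody been rejected.  Trueness is the
mean error, precision the RMSE; `rmse² = me² + var(residuals)` holds to
machine precision.  Method precision is compared by the F-ratio of mean
squared errors (classical over MI) on paired samples, with one-sided
upper-tail p at the per-group usable counts as degrees of freedom (the
published comparison reports only "p < .001"; sidedness and df are this
package's documented choice).  A restricted sample enters the analysis
only if its observed criterion has at least five cases in each category
(the contingency-table rule of thumb); an excluded or non-convergent
sample is excluded for *both* methods, keeping the F-ratio comparison
paired.  True correlations are partitioned into weak [.1, .4),
moderate [.4, .7), strong [.7, .9] for the strength analyses.

## Numerical choices

* Point-biserial uses the population-denominator sd so the identity with
  the product-moment correlation holds exactly.
* Biserial and Case-3 values outside [−1, 1] (possible in finite samples)
  are clipped with a flag.
* Selection count rounds half away from zero; ranking ties break by row
  index (probability zero under continuous draws).
* Non-PSD posterior covariances are repaired by flooring eigenvalues at
  zero; |linear predictor| is capped at 30 (probability saturation).
* One master seed; each iteration × SR cell derives a deterministic child
  stream, so any single cell reproduces in isolation and a full run is a
  pure function of its configuration.
* With identical per-imputation values (nothing missing) the pooled mean
  returns the common value exactly, so full selection is a bit-for-bit
  no-op.

## Problem sizes

The accuracy cells run at the published design size of 5000 Monte Carlo
iterations (the SR = .1 residuals are heavy-tailed after clipping, so
mean errors need that size for small Monte Carlo error); the
monotonicity property suites use 500 iterations per condition, which is
enough for the ordering with a one-inversion tolerance.  Two quantities
are estimated at larger sizes because only the estimate's own noise —
not the quantity — depends on the iteration count: the preliminary-study
RMSE cell at 8000 iterations, and the SR = .9 F-ratio at 30000 (a ratio
of two small MSEs, with seed-to-seed sd ≈ 0.45 at 5000 iterations).
Calibration checks of the generators and the correction oracles use 10⁶
vectorized draws.

## Known limitations

* The posterior of the imputation model is the normal approximation at
  the penalized MLE, not an MCMC posterior; with ≥ 5 cases per category
  and augmentation the difference is negligible for point estimates.
* The F-ratio at high SR compares two small MSEs and converges slowly; at
  1000–2000 iterations its Monte Carlo noise is of order ±10%.
* Under severe restriction (SR = .1) both corrections are biased; the MI
  correction trades more bias there for uniformly better precision.
* The applied mode (`correct_user_dataset`) inherits the assumption that
  selection was strictly top-down on an observed variable; self-selected
  or judgment-selected samples violate MAR and are out of scope.
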