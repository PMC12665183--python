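# Methods

## Model and estimands

We assume the structural outcome model Y = h(X) + U with a continuous
exposure X, unmeasured confounders U, and a single instrument Z satisfying
exchangeability (Z ⫫ U), relevance (Cov(Z, X) ≠ 0), and the exclusion
restriction. The estimands are the effect shape h(x), anchored so that
h(0) = 0 (h(x) is the average causal contrast of moving the exposure from the
reference level 0 to x), and its derivative h′(x), the effect intensity.
Everything in the package estimates h′ first; h is recovered by exact
integration of the fitted basis, so ĥ(0) = 0 holds identically for every
fit.

## Stratification

Both stratification methods select on the counterfactual exposure X(z), not
the observed exposure: X is a common effect of Z and U, so conditioning on X
opens the collider path and breaks within-stratum exchangeability, whereas
X(z) is independent of Z. The residual (prediction) method assumes the
structural exposure model X = t(f(Z) + g(U, ε)) with a known monotone
transform t and linear f; the predicted counterfactual exposure at the
reference level z₀ = 0 is t(t⁻¹(X) − b̂Z), and strata are its equal-size
quantile groups (remainder rows go to the lowest strata). Only the ordering
of the prediction matters for quantile grouping, so the choice z₀ = 0 is
immaterial. The doubly-ranked (matching) method assumes only rank
preservation of X(z) across instrument levels: rows are stably sorted by Z
and cut into ⌊n/K⌋ pre-strata of exactly K consecutive rows (the ≤ K − 1
trailing remainder rows are dropped and counted); within each pre-stratum
exposures are ranked, and stratum k pools the rank-k individuals. Stratum
exposure means are therefore strictly increasing in k. All ties (in Z or X)
are broken by original row order — deterministic, no RNG. A diagnostic
`naive_stratify` (direct exposure quantiles) is included only to demonstrate
the collider bias it induces; the test suite checks that within-stratum
corr(Z, U) is centered at zero for both proper methods and systematically
negative for the naive one.

## Stratum summaries

Within stratum k we compute the slopes α̂ₖ (X on Z) and θ̂ₖ (Y on Z) with
their classical standard errors (closed-form simple-regression algebra,
verified against `scipy.stats.linregress`; the benchmark evaluates on the
order of 10⁵ stratum regressions, so per-call model objects are avoided).
The Wald ratio β̂ₖ = θ̂ₖ/α̂ₖ equals the covariance ratio
Côv(Z,Y|Sₖ)/Côv(Z,X|Sₖ). Its standard error follows the inverse-variance-
weighting conventions: first-order se(θ̂ₖ)/|α̂ₖ| (the default, used in all
benchmarks) or the second-order delta-method form adding the
(θ̂ₖ/α̂ₖ)²se(α̂ₖ)²/α̂ₖ² term. Strata with |α̂ₖ|/se(α̂ₖ) < 2 are flagged as
weak and retained by default (`drop_weak` excludes them); the threshold is a
conventional rule of thumb, not a calibrated test.

The stratum weight function Wₖ(x) = Côv(Z, 1{X ≥ x}|Sₖ)/Côv(Z,X|Sₖ) is stored
as an exact right-continuous step function with breakpoints at the stratum's
distinct exposure values. Its integral telescopes to Côv(Z, X − x_min)/
Côv(Z, X) = 1 exactly on every finite sample, which the tests assert at
1e−10. All inner products used downstream — polynomial moments, indicator
tail masses ∫ₜ^∞ Wₖ, and B-spline products — are computed by exact piecewise
integration (Gauss–Legendre of degree-exact order per step for splines),
never by grid sampling; a dense grid export exists only for plotting. A
parametric alternative (`parametric_weight_function`) discretizes the
N(x̄ₖ, sₖ²) density, appropriate when (Z, X) are close to jointly normal, in
which case W is the exposure density.

Cochran's Q on the stratum Wald ratios against the inverse-variance pooled
estimate, referred to χ²(K−1), serves as the linearity test: under a constant
intensity all strata estimate the same quantity. This is the plain Q
statistic; no trend-augmented variant is implemented.

## Scalar-on-function and scalar-on-scalar regression

With a basis h′(x) = Σₗ bₗφₗ(x), the stratum ratios follow the linear model
β̂ₖ = Σₗ bₗ⟨φₗ, Wₖ⟩ + εₖ with known heteroscedastic noise εₖ ~ N(0, se(β̂ₖ)²).
The penalized weighted least-squares solution is
b̂ = (XᵀΣ⁻¹X + λR)⁻¹XᵀΣ⁻¹β̂ with roughness penalty R_ij = ⟨𝒟ᵐφᵢ, 𝒟ᵐφⱼ⟩ over
the observed exposure range; the coefficient covariance is the sandwich
(XᵀΣ⁻¹X + λR)⁻¹XᵀΣ⁻¹X(XᵀΣ⁻¹X + λR)⁻¹, exact under the stated noise model.
Defaults: penalty order m = 2; λ grid log-spaced 10⁻⁴…10⁴ (17 points) for
GCV, which minimizes (K/(K − tr Hλ)) · (SSEλ/(K − tr Hλ)) on the Σ^{−1/2}-
whitened system, skipping grid points with tr(Hλ) ≥ K. When the basis is
fixed a priori (the oracle polynomial and indicator bases of the benchmarks)
no regularization is needed and λ = 0. The scalar-on-scalar variant replaces
⟨φₗ, Wₖ⟩ with φₗ(x̄ₖ) — accurate when strata are narrow (the designs converge
as K grows, checked in tests) and biased when h′ jumps inside a stratum.
Confidence bands on ĥ(x) = [∫₀ˣφ]ᵀb̂ are pointwise Wald intervals from the
delta method; no simultaneous adjustment is attempted.

Basis families: polynomials (exact moment integrals), B-splines
(scipy.interpolate.BSpline; exact per-step quadrature), and change-point
indicators {1, 1{x ≥ tₚ}} (exact tail masses; the roughness penalty is
undefined for indicators, so R = 0 and λ should stay 0). Indicator bases
accept a `strict` flag (1{x > t}) that only matters when an estimated
intensity is evaluated exactly at a threshold.

## Change-point model and the sum-of-single-effects fit

Choosing indicator knots on a dense candidate grid t₁ < … < t_P (defaults:
the middle-90% percentile grid of X for roughly symmetric exposures; the left
95% percentiles including the minimum for right-skewed ones) gives the sparse
model β̂ₖ = b₀ + Σₚ bₚ∫ₜₚ^∞Wₖ + εₖ, with an intercept slot (t₀ = −∞)
representing a global linear effect. The system is whitened by Σ^{−1/2}
(the noise scale is known from the stratum SEs, so no residual variance is
estimated) and fitted with a sum of L single-effect priors: each effect
selects one candidate (multinomial γ, uniform prior by default) and draws its
coefficient from N(0, σ₀²). The exact single-effect posterior has
closed-form inclusion probabilities π*ₚ ∝ πₚ·BFₚ (Gaussian Bayes factors in
log space) and conditional moments µ*ₚ, σ*ₚ from conjugate simple-regression
algebra; zero-norm design columns (candidates outside all weight supports)
carry zero information and fall back to the prior. Effects are fitted by
IBSS coordinate ascent: residualize against the other effects' posterior
means, apply the single-effect posterior, iterate. Per pass, each effect's
σ₀² is re-profiled by 1-D maximization of its single-effect marginal
likelihood in log σ₀² (bounded search; if no positive value beats the null,
σ₀² = 0 and the effect is inert). Convergence: sup-norm change of the
overall posterior-mean coefficient vector below 10⁻⁶, max 100 passes (a
warning, not an error, on non-convergence). L* counts effects with profiled
σ₀² above 10⁻⁸·Var(whitened response). Defaults L = 10, 10 000 posterior
draws for credible bands. For ≤ 3 candidates and one effect, the posterior
is verified in tests against brute-force enumeration of the exact Gaussian
marginal likelihoods at 10⁻¹⁰.

Two credible-set flavours are reported per detected effect: the
descending-PIP set (smallest prefix reaching 0.95) and the two-sided discrete
quantile interval over candidate values (intercept slot excluded,
renormalized). Change-point point summaries are the posterior mode (NaN if
the intercept slot dominates, i.e. a linear verdict) and the posterior mean
over candidates. When the intercept and the leftmost candidates are nearly
collinear — a ramp starting at the far-left of the support is
indistinguishable from a linear term — PIP mass spreads over that group and
the credible set reports it honestly; this is the expected behaviour under a
truly linear effect, not a failure mode.

Counterfactual predictions use the partial-contrast matrix
f(x*; Xᵢ, tₚ) = (x* − tₚ)₊ − (Xᵢ − tₚ)₊ (intercept slot: x* − Xᵢ):
Ŷᵢ(x*) = Yᵢ + F(x*)·Σₗ(πₗ ∘ µₗ). The posterior effect curve evaluates the
same contrast from the reference level 0, so h(0) = 0 by construction;
pointwise credible bands are Monte-Carlo quantiles over joint posterior draws
(per draw: a candidate per effect from πₗ, a coefficient from the conditional
normal), which at any single grid point reproduces the mixture-of-normals
posterior (verified against analytic mixture-CDF inversion in tests).

## Synthetic data and benchmarks

The generators reproduce three simulation designs built around a weak
instrument. All noise terms (U, ε_X, ε_Y) are standard normal; confounding
enters both X and Y through U.

* Part I: X = 0.15Z + U + ε_X with linear effect Y = X + (confounding) + ε_Y;
  four scenarios crossing binary (Bernoulli(0.5) − 0.5) vs N(0,1) instruments
  with simple (U) vs complex (|U| + ε_X² + 2|U||ε_X|) confounding. n = 5000.
* Part II: binary instrument, two intensity cases at n = 50 000 — a smooth
  case (outcome generator h(X) = X + 0.5X², scored against the design's
  reference intensity 1 + 2x) and a jump case (h(X) = (X)₊, reference
  intensity 1{x > 0}, strict at the threshold).
* Part III: binary/normal instruments crossed with normal
  (X = 0.15Z + U + ε_X) and lognormal (X = exp(0.3Z + U + ε_X)) exposures and
  four effect shapes (linear; one change-point at 0 or 2.5; two change-points;
  smooth quadratic), all anchored at h(0) = 0. n = 50 000. The instrument
  explains ≈ 0.3% (binary) or ≈ 1% (normal) of exposure variance.

Oracle comparators (quadratic effect basis, used as baselines): the
control-function method (residual of X on Z added to the second-stage OLS of
Y on {1, X, X², r}) and the exactly-identified two-parameter IV regression
(2×2 conditional-moment solve over a dichotomized instrument — its two levels
if binary, a median split otherwise). Singular systems raise a fit failure
that the benchmark counts and excludes from the affected cell.

The benchmark evaluates ĥ (Parts I/III) or ĥ′ (Part II) at the closed-form
theoretical exposure quantiles of each scenario (10/30/50/70/90%; normal,
equal-weight normal mixture via root-finding, or their exponentials) and
averages squared errors over replicates, reporting per-cell Monte-Carlo
standard errors. Replicate seeds derive from SeedSequence((master, index)),
making results independent of the joblib worker count. Because the exposure
median is 0 and every fitted curve is anchored at h(0) = 0, the 50% cell of
the Part I/III tables is identically zero — a useful built-in degeneracy
check.

What the generators deliberately do not emulate: invalid instruments
(exclusion-restriction violations), covariates/effect modifiers, coarsened or
measured-with-error exposures, and non-additive confounding in the exposure
model. Passing benchmarks therefore demonstrate correctness of the estimators
under the stated structural models, not robustness to those violations.

## Numerical choices and limitations

* Weight functions, design inner products and curve anchoring are exact;
  there is no integration grid anywhere in the estimation path.
* The 2×2 IV solve declares failure when |det| < 10⁻¹²·max(moments)²; the
  SoF normal equations raise on condition numbers above 10¹² with advice to
  add a penalty.
* The squared error of the weak-IV oracle estimators (ratio-type, binary
  instrument) is heavy-tailed: replicated MSE cells for those methods retain
  visible Monte-Carlo error even at 1000 replicates. The stratification-based
  estimators do not exhibit this instability — within strata the instrument
  split is balanced by construction — which is itself the main scientific
  point of the comparison.
* IBSS is coordinate ascent on a non-convex surface; with strongly correlated
  candidate columns the PIP mass can spread across a correlated group (the
  credible set widens accordingly). Purity filtering of credible sets and
  full ELBO tracking are not implemented.
* Counterfactual predictions assume the fitted change-point model extends to
  the queried exposure level; extrapolating far outside the observed support
  inherits the usual hazards.
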