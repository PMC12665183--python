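# sssiv — stratification-based IV analysis of nonlinear causal effects

`sssiv` estimates *nonlinear* causal effects of a continuous exposure X on an
outcome Y from individual-level data with a single instrumental variable Z —
the setting of Mendelian randomization, where the instrument (a genetic score)
is valid but weak (R² ≈ 0.003–0.01) and often binary or coarsely discrete, so
classical nonlinear IV regression and control-function methods struggle.

It implements a three-stage framework:

1. **Stratification.** The sample is split into K strata on the
   *counterfactual* exposure X(z) rather than the observed exposure (which is
   a collider of Z and the confounders U). Two methods: the *residual*
   (prediction) method, assuming X = t(f(Z) + g(U, ε)); and the
   *doubly-ranked* (matching) method, which only assumes rank preservation —
   sort by Z into pre-strata of size K, rank X within each pre-stratum, and
   pool equal ranks.
2. **Scalar-on-function model.** Each stratum yields a Wald ratio
   β̂ₖ = Côv(Z,Y|Sₖ)/Côv(Z,X|Sₖ) and an estimated weight function
   Wₖ(x) = Côv(Z, 1{X≥x}|Sₖ)/Côv(Z,X|Sₖ), a step function that integrates
   exactly to 1. The ratios obey β̂ₖ = ∫ h′(x)Wₖ(x)dx + εₖ,
   εₖ ~ N(0, se(β̂ₖ)²), where h′ is the effect intensity (the derivative of
   the effect shape h, anchored at h(0) = 0). With a basis expansion
   h′(x) = Σₗ bₗφₗ(x) this is penalized weighted least squares with closed
   form b̂ = (XᵀΣ⁻¹X + λR)⁻¹XᵀΣ⁻¹β̂, λ chosen by GCV; the scalar-on-scalar
   shortcut replaces ⟨φₗ, Wₖ⟩ with φₗ(x̄ₖ).
3. **Sum-of-single-effects change-point model.** Writing
   h′(x) = b₀ + Σₚ bₚ·1{x ≥ tₚ} over a dense candidate grid turns effect-shape
   estimation into sparse regression; a from-scratch SuSiE fit (exact
   single-effect posteriors + IBSS coordinate ascent, per-effect prior
   variance profiled by marginal likelihood) returns posterior inclusion
   probabilities for the change-point locations, credible sets, the number of
   detected change-points L*, posterior effect curves with credible bands,
   and counterfactual outcome predictions.

Supporting modules provide Cochran's-Q linearity testing, simulation
generators for three benchmark designs, oracle comparator estimators
(control function; exactly-identified two-parameter IV regression), and a
replicated MSE benchmark harness.

## Worked example

Detect the change-point in a simulated one-threshold effect
(X lognormal, h(x) = (x − 2.5)₊, weak binary instrument):

```python
import numpy as np
from sssiv import (ScenarioSpec, generate, doubly_ranked_stratify,
                   summarize_strata, linearity_q_test, default_candidates,
                   build_changepoint_design, ibss_fit, posterior_effect_curve)
from sssiv.susie import changepoint_table

gd = generate(ScenarioSpec(part="III", scenario=3, effect_case=2,
                           n=50_000, seed=7))
strata = doubly_ranked_stratify(gd.data, K=100)
summaries = summarize_strata(gd.data, strata, se_order="first")

q, df, p = linearity_q_test(summaries)
print(f"Cochran's Q = {q:.1f} (df={df}), p = {p:.2e}")

design = build_changepoint_design(
    summaries, default_candidates(gd.data.x, style="lognormal"))
fit = ibss_fit(design, L=10)
print(f"detected change-points: L* = {fit.L_star}")
print(changepoint_table(fit)[0])
```

prints (floats truncated here for readability):

```
Cochran's Q = 327.3 (df=99), p = 3.25e-26
detected change-points: L* = 1
{'effect': 1, 'posterior_mode': 2.4103..., 'posterior_mean': 2.4412...,
 'intercept_pip': 9.12e-59, 'pip_set': [73, 74, 75],
 'interval': (2.3151..., 2.6229...)}
```

The Q test rejects a constant effect intensity; SuSiE detects exactly one
change-point with posterior mode 2.41 (truth 2.5) and a 95% credible interval
of (2.32, 2.62). `posterior_effect_curve(fit, grid, n_draws=10_000, rng=1)`
then gives the posterior-mean effect shape with pointwise credible bands,
anchored at h(0) = 0.

The same workflow runs from the shell on any CSV with columns `id,Z,X,Y`:

```bash
sss stratify --input data.csv --method doubly_ranked --K 10 --out strat.csv
sss changepoint --input data.csv --K 100 --L 10 --draws 10000 --seed 7 --out run1
sss fit --input data.csv --model sof --basis poly:2 --lambda auto --out run2
sss bench --part 1 --scenarios 1,3 --methods M1,M2,M3,M5 --reps 200 --seed 11 --out table1.csv
```

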