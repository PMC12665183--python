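"""Sum-of-single-effects change-point model: posteriors, IBSS, inference."""

import numpy as np
import pytest
from scipy import optimize, stats

from sssiv.dataset import IVDataset
from sssiv.susie import (
    SusieFit,
    _partial_contrast,
    build_changepoint_design,
    changepoint_table,
    counterfactual_predict,
    credible_interval,
    credible_set,
    default_candidates,
    ibss_fit,
    point_effect,
    posterior_effect_curve,
    single_effect_posterior,
)
from sssiv.bench import fit_sss, replicate_seed
from sssiv.summaries import estimate_weight_function, StratumSummary
from sssiv.synthetic import ScenarioSpec, generate


def _summary_with_weight(stratum, beta, se, k=1):
    wf = estimate_weight_function(stratum)
    return StratumSummary(k=k, n_k=stratum.n, alpha_hat=1.0, theta_hat=beta,
                          beta_hat=beta, se_beta=se, xbar=float(stratum.x.mean()),
                          weight=wf)


class TestChangePointDesign:
    def test_tail_columns_from_toy_weight(self, toy_stratum):
        summaries = [_summary_with_weight(toy_stratum, 1.0, 0.5)]
        design = build_changepoint_design(summaries, np.array([0.0, 2.5, 9.0]))
        row = design.design[0]
        assert row[0] == 1.0                      # intercept slot
        assert row[1] == pytest.approx(1.0)       # below the support: full mass
        assert row[2] == pytest.approx(0.5)       # 0.5*0.5 + 0.25*1
        assert row[3] == 0.0                      # above the support
        assert np.all(np.diff(row[1:]) <= 0)

    def test_default_candidate_grids(self, rng):
        x = rng.standard_normal(5000)
        mid = default_candidates(x, "normal")
        left = default_candidates(x, "lognormal")
        assert mid.size == 91 and left.size == 96
        assert mid[0] == pytest.approx(np.quantile(x, 0.05))
        assert left[0] == x.min()


class TestSingleEffectPosterior:
    def test_zero_prior_variance_returns_prior(self, rng):
        Xw = rng.standard_normal((10, 3))
        yw = rng.standard_normal(10)
        prior = np.array([0.5, 0.3, 0.2])
        pip, mu, sigma, _ = single_effect_posterior(Xw, yw, 0.0, prior)
        assert np.allclose(pip, prior)
        assert np.allclose(mu, 0.0)
        assert np.allclose(sigma, 0.0)

    @pytest.mark.parametrize("n_cols", [2, 3])
    def test_matches_marginal_likelihood_enumeration(self, rng, n_cols):
        """Independent oracle: pi*_j proportional to pi_j times the exact
        Gaussian marginal likelihood N(y; 0, I + sigma0^2 x_j x_j')."""
        Xw = rng.standard_normal((8, n_cols))
        yw = Xw[:, 0] * 0.8 + 0.3 * rng.standard_normal(8)
        sigma0sq = 0.7
        prior = rng.dirichlet(np.ones(n_cols))
        pip, mu, sigma, _ = single_effect_posterior(Xw, yw, sigma0sq, prior)
        margs = np.array(
            [
                stats.multivariate_normal.logpdf(
                    yw, mean=np.zeros(8),
                    cov=np.eye(8) + sigma0sq * np.outer(Xw[:, j], Xw[:, j]),
                )
                for j in range(n_cols)
            ]
        )
        ref = prior * np.exp(margs - margs.max())
        ref = ref / ref.sum()
        assert np.allclose(pip, ref, atol=1e-10)
        # conditional posteriors against the textbook Bayes regression
        for j in range(n_cols):
            d = Xw[:, j] @ Xw[:, j]
            s2 = 1.0 / d
            post_var = 1.0 / (1.0 / s2 + 1.0 / sigma0sq)
            assert sigma[j] ** 2 == pytest.approx(post_var, rel=1e-12)
            assert mu[j] == pytest.approx(
                post_var * (Xw[:, j] @ yw), rel=1e-10
            )

    def test_dominant_column_absorbs_posterior_mass(self, rng):
        big = 50.0
        x1 = big * rng.standard_normal(20)
        x2 = rng.standard_normal(20)
        yw = x1 * 1.0
        pip, *_ = single_effect_posterior(
            np.column_stack([x1, x2]), yw, 1.0, np.array([0.5, 0.5])
        )
        assert pip[0] > 0.999

    def test_zero_norm_column_is_uninformative(self, rng):
        Xw = np.column_stack([rng.standard_normal(10), np.zeros(10)])
        yw = rng.standard_normal(10)
        pip, mu, sigma, _ = single_effect_posterior(
            Xw, yw, 0.5, np.array([0.5, 0.5])
        )
        assert mu[1] == 0.0
        assert sigma[1] == pytest.approx(np.sqrt(0.5))
        assert np.isfinite(pip).all()


class TestIBSS:
    def _toy_design(self, rng, beta=None, se=0.05, K=30):
        """Strata over a normal exposure with a known coefficient vector."""
        candidates = np.linspace(-1.5, 1.5, 7)
        rows = []
        for k in range(K):
            z = rng.binomial(1, 0.5, 200) - 0.5
            x = rng.standard_normal(200) + (k - K / 2) / (K / 4)
            stratum = IVDataset(z=z, x=0.3 * z + x, y=np.zeros(200))
            wf = estimate_weight_function(stratum)
            rows.append(np.concatenate([[1.0], np.atleast_1d(wf.tail_mass(candidates))]))
        design = np.vstack(rows)
        b = np.zeros(8) if beta is None else np.asarray(beta, dtype=float)
        response = design @ b + rng.normal(0, se, K)
        from sssiv.susie import ChangePointDesign

        return ChangePointDesign(candidates=candidates, design=design,
                                 response=response,
                                 sigma2=np.full(K, se**2))

    def test_pip_rows_normalized_and_intercept_participates(self, rng):
        design = self._toy_design(rng, beta=[2.0, 0, 0, 0, 0, 0, 0, 0])
        fit = ibss_fit(design, L=5)
        assert np.allclose(fit.pip.sum(axis=1), 1.0, atol=1e-10)
        # pure linear effect: the intercept slot dominates one effect
        assert fit.L_star == 1
        lead = int(np.flatnonzero(fit.active)[0])
        assert int(np.argmax(fit.pip[lead])) == 0
        assert fit.posterior_mean_b[0] == pytest.approx(2.0, abs=0.1)

    def test_single_changepoint_detected_at_truth(self, rng):
        # b: intercept 0, jump of 1 at candidate t = 0.0 (index 3 of 7)
        beta = np.zeros(8)
        beta[4] = 1.0
        design = self._toy_design(rng, beta=beta)
        fit = ibss_fit(design, L=10)
        assert fit.L_star == 1
        table = changepoint_table(fit)
        assert table[0]["posterior_mode"] == pytest.approx(0.0, abs=0.51)

    def test_l_equal_one_matches_profiled_single_effect(self, rng):
        from sssiv.susie import _column_stats, _optimize_sigma0sq

        design = self._toy_design(rng, beta=[0, 0, 0, 0, 1.0, 0, 0, 0])
        fit = ibss_fit(design, L=1)
        s = np.sqrt(design.sigma2)
        Xw = design.design / s[:, None]
        yw = design.response / s
        prior = np.full(8, 1 / 8)
        bhat, s2 = _column_stats(Xw, yw)
        v = _optimize_sigma0sq(bhat, s2, prior)
        pip, mu, sigma, _ = single_effect_posterior(Xw, yw, v, prior)
        assert np.allclose(fit.pip[0], pip, atol=1e-8)
        assert np.allclose(fit.mu[0], mu, atol=1e-8)

    def test_insensitive_to_l_on_one_changepoint_fixture(self):
        gd = generate(ScenarioSpec(part="III", scenario=1, effect_case=2,
                                   n=20_000, seed=replicate_seed(2, 0)))
        sets, lstars = [], []
        for L in (5, 10, 20):
            fit, _ = fit_sss(gd.data, K=50, L=L, style="normal")
            lstars.append(fit.L_star)
            lead = int(np.flatnonzero(fit.active)[0])
            sets.append(tuple(credible_set(fit.pip[lead], 0.95)))
        assert lstars == [1, 1, 1]
        assert sets[0] == sets[1] == sets[2]


class TestCredibleSets:
    def test_high_pip_singleton(self):
        assert credible_set(np.array([0.97, 0.02, 0.01])) == [0]

    def test_uniform_twenty_candidates_drop_one(self):
        assert len(credible_set(np.full(20, 0.05))) == 19

    def test_cumulative_mass_enumeration(self):
        assert credible_set(np.array([0.5, 0.3, 0.2]), 0.95) == [0, 1, 2]

    def test_interval_covers_central_mass(self):
        pip_row = np.array([0.0, 0.02, 0.1, 0.76, 0.1, 0.02])
        cands = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        lo, hi = credible_interval(pip_row, cands, 0.95)
        # smallest discrete quantile bracket: cumulative mass 0.02 below 2.0
        # and 0.98 through 4.0
        assert lo == 2.0 and hi == 4.0
        inside = (cands >= lo) & (cands <= hi)
        assert pip_row[1:][inside].sum() >= 0.95


class TestCounterfactuals:
    def test_partial_contrast_identities(self):
        cands = np.array([2.0])
        F = _partial_contrast(3.0, np.array([1.0]), cands)
        assert F[0, 0] == 2.0            # intercept slot: x* - X_i
        assert F[0, 1] == 1.0            # (3-2)+ - (1-2)+ = 1
        assert np.allclose(_partial_contrast(1.0, np.array([1.0]), cands), 0.0)

    def _certain_fit(self, mode_value=2.0, b=1.5, sd=0.0):
        pip = np.array([[0.0, 1.0]])
        mu = np.array([[0.0, b]])
        sigma = np.array([[0.0, sd]])
        return SusieFit(candidates=np.array([mode_value]), pip=pip, mu=mu,
                        sigma=sigma, prior_var=np.array([1.0]),
                        prior_pi=np.array([0.5, 0.5]), L=1, _inert_tol=1e-12)

    def test_degenerate_posterior_counterfactual(self, rng):
        fit = self._certain_fit(mode_value=2.0, b=1.5)
        x = rng.uniform(0, 4, 50)
        y = rng.standard_normal(50)
        data = IVDataset(z=np.tile([0.0, 1.0], 25), x=x, y=y)
        got = counterfactual_predict(fit, data, x_star=3.0)
        expected = y + 1.5 * (np.maximum(3.0 - 2.0, 0) - np.maximum(x - 2.0, 0))
        assert np.allclose(got, expected)

    def test_no_intervention_returns_observed_outcome(self, rng):
        fit = self._certain_fit()
        data = IVDataset(z=np.tile([0.0, 1.0], 10),
                         x=np.full(20, 1.3), y=rng.standard_normal(20))
        assert np.allclose(counterfactual_predict(fit, data, 1.3), data.y)


class TestPosteriorEffectCurve:
    def test_zero_grid_point_is_anchored(self):
        fit = TestCounterfactuals()._certain_fit()
        curve = posterior_effect_curve(fit, np.array([0.0]), n_draws=1000,
                                       rng=1)
        assert curve.h[0] == 0.0
        assert curve.lower[0] == curve.upper[0] == 0.0

    def test_certain_effect_reproduces_ramp_with_zero_width_band(self):
        fit = TestCounterfactuals()._certain_fit(mode_value=2.0, b=1.0, sd=0.0)
        grid = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        curve = posterior_effect_curve(fit, grid, n_draws=1000, rng=1)
        ramp = np.maximum(grid - 2.0, 0.0)
        assert np.allclose(curve.h, ramp)
        assert np.allclose(curve.lower, ramp)
        assert np.allclose(curve.upper, ramp)

    def test_band_matches_analytic_mixture_quantiles(self):
        # one effect, two slots: with prob 0.4 a linear term b0 ~ N(1, 0.2^2)
        # (contribution x*b0), with prob 0.6 a ramp at t=1, b1 ~ N(2, 0.3^2)
        pip = np.array([[0.4, 0.6]])
        mu = np.array([[1.0, 2.0]])
        sigma = np.array([[0.2, 0.3]])
        fit = SusieFit(candidates=np.array([1.0]), pip=pip, mu=mu, sigma=sigma,
                       prior_var=np.array([1.0]), prior_pi=np.array([0.5, 0.5]),
                       L=1, _inert_tol=1e-12)
        x = 3.0
        f = np.array([x, max(x - 1.0, 0.0)])  # (3, 2)
        curve = posterior_effect_curve(fit, np.array([x]), n_draws=400_000,
                                       rng=7)

        def mix_cdf(v):
            return 0.4 * stats.norm.cdf(v, f[0] * 1.0, f[0] * 0.2) + \
                   0.6 * stats.norm.cdf(v, f[1] * 2.0, f[1] * 0.3)

        lo_ref = optimize.brentq(lambda v: mix_cdf(v) - 0.025, -10, 20)
        hi_ref = optimize.brentq(lambda v: mix_cdf(v) - 0.975, -10, 20)
        assert curve.lower[0] == pytest.approx(lo_ref, abs=0.02)
        assert curve.upper[0] == pytest.approx(hi_ref, abs=0.02)
        assert curve.h[0] == pytest.approx(0.4 * f[0] * 1.0 + 0.6 * f[1] * 2.0,
                                           abs=1e-12)

    def test_point_effect_matches_curve(self):
        fit = TestCounterfactuals()._certain_fit(mode_value=1.0, b=0.5)
        grid = np.linspace(-1, 3, 9)
        curve = posterior_effect_curve(fit, grid, n_draws=1000, rng=0)
        assert np.allclose(point_effect(fit, grid), curve.h)
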