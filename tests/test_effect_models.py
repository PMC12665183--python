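"""SoF/SoS regression: exact designs, GLS algebra, GCV, curve reconstruction."""

import numpy as np
import pytest

from sssiv.dataset import IVDataset
from sssiv.effect_models import (
    BasisSpec,
    SoFFit,
    build_sof_design,
    build_sos_design,
    fit_sof,
    fit_sos,
    reconstruct_curve,
    select_lambda_gcv,
)
from sssiv.stratify import doubly_ranked_stratify
from sssiv.summaries import StratumSummary, estimate_weight_function, summarize_strata


def _summary(beta, se, xbar=0.0, weight=None, k=1):
    return StratumSummary(k=k, n_k=10, alpha_hat=1.0, theta_hat=beta,
                          beta_hat=beta, se_beta=se, xbar=xbar, weight=weight)


@pytest.fixture
def toy_summaries(toy_stratum):
    """Five strata sharing the hand-computable 4-point weight function."""
    wf = estimate_weight_function(toy_stratum)
    rng = np.random.default_rng(5)
    return [
        _summary(beta=float(b), se=float(s), xbar=float(x), weight=wf, k=i + 1)
        for i, (b, s, x) in enumerate(
            zip(rng.normal(1, 0.5, 5), rng.uniform(0.2, 0.8, 5),
                np.linspace(-1, 1, 5))
        )
    ]


class TestDesigns:
    def test_constant_basis_column_is_ones(self, toy_summaries):
        skel = build_sof_design(toy_summaries, BasisSpec("polynomial", degree=2))
        assert np.allclose(skel.design[:, 0], 1.0, atol=1e-12)

    def test_linear_inner_product_by_hand(self, toy_summaries):
        skel = build_sof_design(toy_summaries, BasisSpec("polynomial", degree=1))
        # <x, W> = 0.25*1.5 + 0.5*2.5 + 0.25*3.5 = 2.5
        assert np.allclose(skel.design[:, 1], 2.5, atol=1e-12)

    def test_indicator_tail_masses_monotone(self, toy_summaries):
        basis = BasisSpec("changepoint_indicators",
                          candidates=np.linspace(0.0, 5.0, 11))
        skel = build_sof_design(toy_summaries, basis)
        tails = skel.design[:, 1:]
        assert np.all((tails >= 0) & (tails <= 1))
        assert np.all(np.diff(tails, axis=1) <= 1e-15)

    def test_sos_design_evaluates_basis_at_stratum_means(self, toy_summaries):
        skel = build_sos_design(toy_summaries, BasisSpec("polynomial", degree=2))
        xbar = np.array([s.xbar for s in toy_summaries])
        assert np.allclose(skel.design[:, 1], xbar)
        assert np.allclose(skel.design[:, 2], xbar**2)

    def test_bspline_support_must_cover_weights(self, toy_summaries):
        basis = BasisSpec("bspline", degree=3, knots=np.linspace(1.5, 4.0, 5))
        with pytest.raises(ValueError, match="stratum"):
            build_sof_design(toy_summaries, basis)

    def test_sof_sos_agree_in_narrow_stratum_limit(self, linear_iv_data):
        basis = BasisSpec("polynomial", degree=1)

        def max_gap(K):
            a = doubly_ranked_stratify(linear_iv_data, K)
            summaries = summarize_strata(linear_iv_data, a, weights=True)
            sof = build_sof_design(summaries, basis).design
            sos = build_sos_design(summaries, basis).design
            return np.max(np.abs(sof - sos))

        # the inner product <x, W_k> approaches phi(xbar_k) = xbar_k as the
        # strata narrow; edge strata converge slowest, so compare means too
        def mean_gap(K):
            a = doubly_ranked_stratify(linear_iv_data, K)
            summaries = summarize_strata(linear_iv_data, a, weights=True)
            sof = build_sof_design(summaries, basis).design
            sos = build_sos_design(summaries, basis).design
            return np.mean(np.abs(sof - sos))

        assert max_gap(100) < max_gap(10)
        assert mean_gap(100) < mean_gap(10)
        assert mean_gap(100) < 0.05


class TestFitSof:
    def test_single_constant_basis_collapses_to_ivw(self, toy_summaries):
        skel = build_sof_design(toy_summaries, BasisSpec("polynomial", degree=0))
        fit = fit_sof(skel, lam=0.0)
        w = 1 / np.array([s.se_beta**2 for s in toy_summaries])
        betas = np.array([s.beta_hat for s in toy_summaries])
        assert fit.b_hat[0] == pytest.approx(w @ betas / w.sum(), abs=1e-12)
        assert fit.cov_b[0, 0] == pytest.approx(1 / w.sum(), abs=1e-12)

    def test_matches_independent_gls_solve(self):
        rng = np.random.default_rng(17)
        X = rng.standard_normal((5, 3))
        sigma2 = rng.uniform(0.2, 2.0, 5)
        y = rng.standard_normal(5)
        skel = SoFFit(design=X, sigma2=sigma2, response=y,
                      basis=BasisSpec("polynomial", degree=2), domain=(-1, 1))
        fit = fit_sof(skel, lam=0.0)
        # independent whitened least-squares oracle
        Xw = X / np.sqrt(sigma2)[:, None]
        yw = y / np.sqrt(sigma2)
        b_ref, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        cov_ref = np.linalg.inv(Xw.T @ Xw)
        assert np.allclose(fit.b_hat, b_ref, atol=1e-10)
        assert np.allclose(fit.cov_b, cov_ref, atol=1e-10)

    def test_heavy_penalty_shrinks_to_null_space(self, toy_summaries):
        # m=1 on a polynomial basis: the penalty null space is the constants
        skel = build_sos_design(toy_summaries, BasisSpec("polynomial", degree=2))
        fit = fit_sof(skel, lam=1e10, m=1)
        assert abs(fit.b_hat[1]) < 1e-6
        assert abs(fit.b_hat[2]) < 1e-6

    def test_singular_design_advises_penalty(self, toy_summaries):
        # duplicated candidates give identical columns
        basis = BasisSpec("changepoint_indicators",
                          candidates=np.array([2.0, 2.0 + 1e-15, 2.4, 2.6]))
        skel = build_sof_design(toy_summaries, basis)
        with pytest.raises(np.linalg.LinAlgError, match="penalty"):
            fit_sof(skel, lam=0.0)

    def test_constant_response_yields_constant_intensity(self):
        summaries = [_summary(beta=1.7, se=0.5, xbar=x, k=i + 1)
                     for i, x in enumerate(np.linspace(-2, 2, 6))]
        fit = fit_sos(summaries, BasisSpec("polynomial", degree=1), lam=0.0)
        assert fit.b_hat[0] == pytest.approx(1.7, abs=1e-10)
        assert fit.b_hat[1] == pytest.approx(0.0, abs=1e-10)


class TestGCV:
    @staticmethod
    def _brute_force_gcv(skel, lam, m):
        s = np.sqrt(skel.sigma2)
        Xw = skel.design / s[:, None]
        yw = skel.response / s
        R = skel.basis.penalty(m, skel.domain)
        H = Xw @ np.linalg.inv(Xw.T @ Xw + lam * R) @ Xw.T
        K = skel.design.shape[0]
        tr = np.trace(H)
        sse = float(np.sum((yw - H @ yw) ** 2))
        return (K / (K - tr)) * (sse / (K - tr)), tr

    def test_trace_at_zero_penalty_equals_basis_size(self, toy_summaries):
        skel = build_sos_design(toy_summaries, BasisSpec("polynomial", degree=2))
        _, tr = self._brute_force_gcv(skel, 0.0, 2)
        assert tr == pytest.approx(3.0, abs=1e-9)

    def test_single_candidate_grid_returned(self, toy_summaries):
        skel = build_sos_design(toy_summaries, BasisSpec("polynomial", degree=1))
        assert select_lambda_gcv(skel, lambda_grid=np.array([0.37])) == 0.37

    def test_selected_lambda_minimizes_brute_force_criterion(self):
        rng = np.random.default_rng(3)
        xbar = np.linspace(-2, 2, 20)
        truth = 1 + 0.5 * xbar  # smooth intensity
        summaries = [
            _summary(beta=float(t + rng.normal(0, 0.4)), se=0.4, xbar=float(x),
                     k=i + 1)
            for i, (t, x) in enumerate(zip(truth, xbar))
        ]
        skel = build_sos_design(summaries, BasisSpec("polynomial", degree=3))
        grid = np.logspace(-3, 3, 9)
        lam = select_lambda_gcv(skel, m=2, lambda_grid=grid)
        scores = [self._brute_force_gcv(skel, g, 2)[0] for g in grid]
        assert lam == grid[int(np.argmin(scores))]
        # GCV-selected fit sits between the un- and over-penalized extremes
        sse = {
            g: float(
                np.sum(
                    (skel.response - skel.design @ fit_sof(skel, g, 2).b_hat) ** 2
                    / skel.sigma2
                )
            )
            for g in (0.0, lam, 1e8)
        }
        assert sse[0.0] <= sse[lam] <= sse[1e8]


class TestReconstructCurve:
    def test_constant_intensity_integrates_to_identity(self, toy_summaries):
        skel = build_sos_design(toy_summaries, BasisSpec("polynomial", degree=1))
        fit = fit_sof(skel, lam=0.0)
        fit.b_hat = np.array([1.0, 0.0])
        grid = np.linspace(-2, 3, 11)
        curve = reconstruct_curve(fit, grid)
        assert np.allclose(curve.h, grid, atol=1e-12)
        assert np.allclose(curve.h_prime, 1.0)
        assert curve.h[np.searchsorted(grid, 0.0)] == 0.0

    def test_changepoint_antiderivative_is_ramp(self, toy_summaries):
        basis = BasisSpec("changepoint_indicators", candidates=np.array([2.0]))
        skel = build_sof_design(toy_summaries, basis)
        skel.b_hat = np.array([0.0, 1.0])
        skel.cov_b = np.zeros((2, 2))
        grid = np.array([0.0, 1.0, 2.0, 3.5])
        curve = reconstruct_curve(skel, grid)
        assert np.allclose(curve.h, np.maximum(grid - 2.0, 0.0), atol=1e-12)

    def test_band_width_scales_with_coefficient_uncertainty(self, toy_summaries):
        skel = build_sos_design(toy_summaries, BasisSpec("polynomial", degree=1))
        fit = fit_sof(skel, lam=0.0)
        grid = np.linspace(-1, 1, 5)
        narrow = reconstruct_curve(fit, grid)
        fit.cov_b = fit.cov_b * 4.0
        wide = reconstruct_curve(fit, grid)
        mask = grid != 0.0
        assert np.all(
            (wide.upper - wide.lower)[mask] > (narrow.upper - narrow.lower)[mask]
        )

    def test_bspline_basis_recovers_smooth_intensity(self, rng):
        # strata with known smooth intensity read off at the means
        xbar = np.linspace(-2, 2, 30)
        beta = 1 + 2 * xbar + rng.normal(0, 0.05, xbar.size)
        summaries = [_summary(float(b), 0.05, float(x), k=i + 1)
                     for i, (b, x) in enumerate(zip(beta, xbar))]
        basis = BasisSpec("bspline", degree=3, knots=np.linspace(-2.5, 2.5, 6))
        fit = fit_sos(summaries, basis, lam=1e-6)
        grid = np.linspace(-1.5, 1.5, 7)
        curve = reconstruct_curve(fit, grid)
        assert np.allclose(curve.h_prime, 1 + 2 * grid, atol=0.15)
        assert curve.h[3] == pytest.approx(0.0, abs=1e-10)  # grid[3] == 0


class TestQuadraticRecovery:
    def test_intensity_coefficients_recovered_with_strong_instrument(self, rng):
        # h(x) = x + x^2 so the intensity basis {1, x} has b = (1, 2);
        # a strong instrument keeps the stratum Wald ratios precise
        n = 20_000
        z = rng.standard_normal(n)
        u = rng.standard_normal(n)
        x = z + u + rng.standard_normal(n)
        y = x + x**2 + u + rng.standard_normal(n)
        data = IVDataset(z=z, x=x, y=y)
        a = doubly_ranked_stratify(data, 50)
        summaries = summarize_strata(data, a, weights=False)
        fit = fit_sos(summaries, BasisSpec("polynomial", degree=1), lam=0.0)
        assert fit.b_hat[0] == pytest.approx(1.0, abs=0.25)
        assert fit.b_hat[1] == pytest.approx(2.0, abs=0.25)
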