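"""Sum-of-single-effects (SuSiE) fitting of the change-point effect model.

Writing the effect intensity as piecewise constant over candidate thresholds,
h'(x) = sum_p b_p I{x >= t_p} (slot p = 0 is an intercept, the potential
globally linear effect), the scalar-on-function regression becomes the sparse
linear model

    beta_k = b_0 + sum_p b_p * int_{t_p}^inf W_k(x) dx + eps_k,
    eps_k ~ N(0, se_k^2),

with typically many more candidates than strata but few nonzero b_p (one per
true change-point).  SuSiE places L independent "single effect" priors on b —
each effect selects exactly one candidate (multinomial gamma with prior pi)
and gives it a N(0, sigma0^2) coefficient — and fits them by Iterative
Bayesian Stepwise Selection (IBSS): coordinate ascent that residualizes each
effect against the others and applies the exact single-effect posterior.
Each effect's prior variance sigma0^2 is re-estimated every pass by
maximizing its single-effect marginal likelihood; effects whose optimal
sigma0^2 collapses to zero are inert, and the number of surviving effects
L* estimates the number of change-points.

The heteroscedastic system is premultiplied by Sigma^{-1/2} (the standard
errors are known from the stratum fits), reducing to a unit-variance SuSiE
regression.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import logsumexp

from .dataset import IVDataset
from .curves import EffectCurve
from .summaries import StratumSummary

logger = logging.getLogger(__name__)

__all__ = [
    "ChangePointDesign",
    "SusieFit",
    "build_changepoint_design",
    "default_candidates",
    "single_effect_posterior",
    "ibss_fit",
    "credible_set",
    "credible_interval",
    "counterfactual_predict",
    "posterior_effect_curve",
    "changepoint_table",
]


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------


@dataclass
class ChangePointDesign:
    """Tail-mass design of the change-point model.

    Column 0 is all ones (intercept slot, semantics t_0 = -inf); column p is
    the exact tail integral of each stratum's weight function beyond t_p, an
    elementwise-[0,1] quantity nonincreasing in p within each row.
    """

    candidates: np.ndarray            # (P,) sorted thresholds t_1..t_P
    design: np.ndarray                # (K, P+1)
    response: np.ndarray              # (K,) stratum Wald ratios
    sigma2: np.ndarray                # (K,) diagonal of Sigma

    @property
    def P(self) -> int:
        return self.candidates.size

    @property
    def K(self) -> int:
        return self.design.shape[0]


def default_candidates(x: np.ndarray, style: str = "normal") -> np.ndarray:
    """Percentile-grid change-point candidates.

    style="normal":    middle 90% sample quantiles (5%..95%, step 1%).
    style="lognormal": left 95% sample quantiles including the minimum
                       (0%..95%), suited to right-skewed exposures.
    """
    x = np.asarray(x, dtype=float)
    if style == "normal":
        probs = np.arange(5, 96) / 100.0
    elif style == "lognormal":
        probs = np.arange(0, 96) / 100.0
    else:
        raise ValueError(f"unknown candidate style {style!r}")
    return np.unique(np.quantile(x, probs))


def build_changepoint_design(
    summaries: list[StratumSummary], candidates: np.ndarray
) -> ChangePointDesign:
    """Exact tail integrals of every stratum weight at every candidate."""
    candidates = np.sort(np.asarray(candidates, dtype=float))
    rows = []
    for s in summaries:
        if s.weight is None:
            raise ValueError(f"stratum {s.k} has no weight function")
        tails = np.atleast_1d(s.weight.tail_mass(candidates))
        rows.append(np.concatenate([[1.0], tails]))
    design = np.vstack(rows)
    degenerate = np.flatnonzero(
        (np.ptp(design[:, 1:], axis=0) == 0.0)
    )
    if degenerate.size:
        logger.info(
            "%d change-point candidates fall outside all weight supports "
            "(constant design column)", degenerate.size
        )
    response = np.array([s.beta_hat for s in summaries])
    sigma2 = np.array([s.se_beta**2 for s in summaries])
    return ChangePointDesign(
        candidates=candidates, design=design, response=response, sigma2=sigma2
    )


# ---------------------------------------------------------------------------
# single-effect posterior
# ---------------------------------------------------------------------------


def _column_stats(Xw: np.ndarray, yw: np.ndarray):
    """Per-column WLS estimate and sampling variance on the whitened system."""
    d = np.einsum("ij,ij->j", Xw, Xw)
    ok = d > 0
    bhat = np.zeros(Xw.shape[1])
    s2 = np.full(Xw.shape[1], np.inf)
    bhat[ok] = (Xw.T @ yw)[ok] / d[ok]
    s2[ok] = 1.0 / d[ok]
    return bhat, s2


def _log_bf(bhat: np.ndarray, s2: np.ndarray, sigma0sq: float) -> np.ndarray:
    """Exact Gaussian log Bayes factor of b ~ N(0, sigma0^2) vs b = 0."""
    if sigma0sq == 0.0:
        return np.zeros_like(bhat)
    finite = np.isfinite(s2)
    out = np.zeros_like(bhat)
    s2f = s2[finite]
    out[finite] = 0.5 * np.log(s2f / (s2f + sigma0sq)) + 0.5 * (
        bhat[finite] ** 2 / s2f
    ) * (sigma0sq / (sigma0sq + s2f))
    return out


def _log_prior(prior_pi: np.ndarray) -> np.ndarray:
    out = np.full_like(np.asarray(prior_pi, dtype=float), -np.inf)
    np.log(prior_pi, out=out, where=np.asarray(prior_pi) > 0)
    return out


def single_effect_posterior(
    Xw: np.ndarray,
    yw: np.ndarray,
    sigma0sq: float,
    prior_pi: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Posterior of one single-effect model on the whitened system.

    Returns (pip, mu, sigma, loglik_excess): the posterior inclusion
    probabilities pi*_p (normalized over candidates), the conditional
    posterior means mu*_p and sds sigma*_p given inclusion, and the
    log marginal likelihood relative to the null b = 0.
    All Bayes-factor work is done in log space.
    """
    if sigma0sq < 0:
        raise ValueError("sigma0sq must be nonnegative")
    bhat, s2 = _column_stats(Xw, yw)
    log_bf = _log_bf(bhat, s2, sigma0sq)
    log_post = _log_prior(prior_pi) + log_bf
    norm = logsumexp(log_post)
    pip = np.exp(log_post - norm)
    if sigma0sq == 0.0:
        mu = np.zeros_like(bhat)
        sigma = np.zeros_like(bhat)
    else:
        finite = np.isfinite(s2)
        post_var = np.zeros_like(bhat)
        mu = np.zeros_like(bhat)
        post_var[finite] = 1.0 / (1.0 / s2[finite] + 1.0 / sigma0sq)
        mu[finite] = post_var[finite] * bhat[finite] / s2[finite]
        post_var[~finite] = sigma0sq  # data carry no information on the column
        sigma = np.sqrt(post_var)
    return pip, mu, sigma, float(norm)


def _optimize_sigma0sq(
    bhat: np.ndarray, s2: np.ndarray, prior_pi: np.ndarray
) -> float:
    """Profile the single-effect prior variance by marginal likelihood.

    1-D maximization in log sigma0^2, lower-bounded at 0: if no positive
    variance beats the null marginal likelihood, the effect is inert and
    sigma0^2 = 0 is returned.
    """
    log_w = _log_prior(prior_pi)

    def neg_loglik(log_v: float) -> float:
        return -float(logsumexp(log_w + _log_bf(bhat, s2, np.exp(log_v))))

    res = optimize.minimize_scalar(
        neg_loglik, bounds=(-30.0, 15.0), method="bounded",
        options={"xatol": 1e-8},
    )
    # null marginal loglik (sigma0^2 = 0) is exactly 0 on this scale
    if -res.fun > 1e-12:
        return float(np.exp(res.x))
    return 0.0


# ---------------------------------------------------------------------------
# IBSS
# ---------------------------------------------------------------------------


@dataclass
class SusieFit:
    """Posterior summaries of the fitted sum-of-single-effects model."""

    candidates: np.ndarray             # (P,) thresholds (intercept slot excluded)
    pip: np.ndarray                    # (L, P+1) posterior inclusion probabilities
    mu: np.ndarray                     # (L, P+1) conditional posterior means
    sigma: np.ndarray                  # (L, P+1) conditional posterior sds
    prior_var: np.ndarray              # (L,) profiled sigma0^2 per effect
    prior_pi: np.ndarray               # (P+1,)
    L: int = 10
    converged: bool = True
    n_iter: int = 0

    @property
    def active(self) -> np.ndarray:
        return self.prior_var > self._inert_tol

    _inert_tol: float = field(default=0.0, repr=False)

    @property
    def L_star(self) -> int:
        return int(self.active.sum())

    @property
    def posterior_mean_b(self) -> np.ndarray:
        """Overall posterior-mean coefficient vector sum_l pip_l * mu_l."""
        return (self.pip * self.mu).sum(axis=0)

    def pip_frame(self, active_only: bool = True) -> pd.DataFrame:
        rows = np.flatnonzero(self.active) if active_only else np.arange(self.L)
        cols = ["intercept"] + [f"t={t:.6g}" for t in self.candidates]
        return pd.DataFrame(self.pip[rows], index=[f"effect_{r+1}" for r in rows],
                            columns=cols)


def ibss_fit(
    design: ChangePointDesign,
    L: int = 10,
    prior_pi: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> SusieFit:
    """Iterative Bayesian Stepwise Selection for the change-point model.

    Coordinate ascent over effects l = 1..L: the expected contribution of all
    other effects is subtracted from the (whitened) response, the exact
    single-effect posterior is applied to the residual, and the effect's
    prior variance sigma0^2 is re-profiled each pass.  Stops when the overall
    posterior-mean coefficient vector changes by less than ``tol`` in sup
    norm, or at ``max_iter`` with a warning.
    """
    if L < 1:
        raise ValueError("L must be at least 1")
    P1 = design.P + 1
    if prior_pi is None:
        prior_pi = np.full(P1, 1.0 / P1)
    prior_pi = np.asarray(prior_pi, dtype=float)
    if prior_pi.size != P1 or np.any(prior_pi < 0):
        raise ValueError("prior_pi must be a nonnegative vector of length P+1")
    prior_pi = prior_pi / prior_pi.sum()

    s = np.sqrt(design.sigma2)
    Xw = design.design / s[:, None]
    yw = design.response / s

    pip = np.tile(prior_pi, (L, 1))
    mu = np.zeros((L, P1))
    sigma = np.zeros((L, P1))
    prior_var = np.zeros(L)
    fitted = np.zeros((L, design.K))   # Xw @ (pip_l * mu_l) per effect

    b_bar_prev = np.zeros(P1)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for l in range(L):
            r_l = yw - fitted.sum(axis=0) + fitted[l]
            bhat, s2 = _column_stats(Xw, r_l)
            v = _optimize_sigma0sq(bhat, s2, prior_pi)
            prior_var[l] = v
            pip[l], mu[l], sigma[l], _ = single_effect_posterior(
                Xw, r_l, v, prior_pi
            )
            fitted[l] = Xw @ (pip[l] * mu[l])
        b_bar = (pip * mu).sum(axis=0)
        if np.max(np.abs(b_bar - b_bar_prev)) < tol:
            converged = True
            break
        b_bar_prev = b_bar
    if not converged:
        warnings.warn(
            f"IBSS did not converge in {max_iter} iterations; returning the "
            "last iterate", stacklevel=2
        )
    inert_tol = 1e-8 * float(np.var(yw))
    return SusieFit(
        candidates=design.candidates,
        pip=pip,
        mu=mu,
        sigma=sigma,
        prior_var=prior_var,
        prior_pi=prior_pi,
        L=L,
        converged=converged,
        n_iter=it,
        _inert_tol=inert_tol,
    )


# ---------------------------------------------------------------------------
# credible sets and summaries
# ---------------------------------------------------------------------------


def credible_set(pip_row: np.ndarray, level: float = 0.95) -> list[int]:
    """Smallest descending-PIP prefix with cumulative mass >= level.

    Returns candidate-slot indices (0 = intercept); ties broken by slot order.
    """
    pip_row = np.asarray(pip_row, dtype=float)
    order = np.argsort(-pip_row, kind="stable")
    cum = np.cumsum(pip_row[order])
    cut = int(np.searchsorted(cum, level - 1e-12)) + 1
    return sorted(order[:cut].tolist())


def credible_interval(
    pip_row: np.ndarray, candidates: np.ndarray, level: float = 0.95
) -> tuple[float, float]:
    """Two-sided interval of candidate values with ``level`` cumulative mass.

    The intercept slot is excluded and the remaining mass renormalized; the
    bounds are the (1-level)/2 and (1+level)/2 quantiles of the discrete
    posterior over the candidate thresholds.
    """
    mass = np.asarray(pip_row, dtype=float)[1:]
    if mass.sum() <= 0:
        return (np.nan, np.nan)
    mass = mass / mass.sum()
    cum = np.cumsum(mass)
    alpha = (1.0 - level) / 2.0
    lo = candidates[int(np.searchsorted(cum, alpha))]
    hi = candidates[min(int(np.searchsorted(cum, 1.0 - alpha)), mass.size - 1)]
    return float(lo), float(hi)


def changepoint_table(fit: SusieFit, level: float = 0.95) -> list[dict]:
    """Per-detected-effect change-point summaries.

    For each active effect: the posterior mode (candidate with maximal PIP;
    NaN if the intercept slot dominates, i.e. the effect is linear), the
    posterior mean over candidate values, and both credible-set flavors.
    """
    out = []
    for l in np.flatnonzero(fit.active):
        row = fit.pip[l]
        slot = int(np.argmax(row))
        mode = np.nan if slot == 0 else float(fit.candidates[slot - 1])
        tail = row[1:]
        mean = float(tail @ fit.candidates / tail.sum()) if tail.sum() > 0 else np.nan
        out.append(
            {
                "effect": int(l + 1),
                "posterior_mode": mode,
                "posterior_mean": mean,
                "intercept_pip": float(row[0]),
                "pip_set": credible_set(row, level),
                "interval": credible_interval(row, fit.candidates, level),
            }
        )
    return out


# ---------------------------------------------------------------------------
# counterfactuals and posterior effect curve
# ---------------------------------------------------------------------------


def _partial_contrast(x_star: float, x_from: np.ndarray, candidates: np.ndarray):
    """Matrix f(x*; x_i, t_p) = (x*-t_p)_+ - (x_i-t_p)_+, intercept slot = x*-x_i."""
    x_from = np.atleast_1d(np.asarray(x_from, dtype=float))
    cols = [x_star - x_from]
    for t in candidates:
        cols.append(max(x_star - t, 0.0) - np.maximum(x_from - t, 0.0))
    return np.column_stack(cols)


def counterfactual_predict(
    fit: SusieFit, data: IVDataset, x_star: float
) -> np.ndarray:
    """Posterior-mean counterfactual outcomes Y_i(x*) = Y_i + F(x*) b_bar."""
    F = _partial_contrast(x_star, data.x, fit.candidates)
    return data.y + F @ fit.posterior_mean_b


def point_effect(fit: SusieFit, grid: np.ndarray) -> np.ndarray:
    """Posterior-mean effect shape h(x) = f(x)' sum_l (pip_l * mu_l), h(0)=0."""
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    Fg = np.vstack(
        [_partial_contrast(float(g), np.zeros(1), fit.candidates) for g in grid]
    )
    return Fg @ fit.posterior_mean_b


def posterior_effect_curve(
    fit: SusieFit,
    grid: np.ndarray,
    n_draws: int = 10_000,
    level: float = 0.95,
    rng: np.random.Generator | int | None = None,
) -> EffectCurve:
    """Posterior effect shape h(x) on a grid, with Monte-Carlo credible band.

    The point estimate is the posterior mean h(x) = f(x)' sum_l (pip_l*mu_l)
    with f(x)_p = (x-t_p)_+ - (0-t_p)_+ (intercept slot: x); h(0) = 0 by
    construction.  The band samples, per draw and per active effect, a
    candidate slot from pip_l and a coefficient from the conditional normal,
    sums the effect contributions across the grid, and takes the pointwise
    (1-level)/2 and (1+level)/2 quantiles — the mixture-of-normals posterior
    of each h(x).
    """
    if n_draws < 1000:
        raise ValueError("use at least 1000 posterior draws")
    rng = np.random.default_rng(rng)
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    # f(x; 0, t_p) per grid point, intercept slot = x
    Fg = np.vstack(
        [_partial_contrast(float(g), np.zeros(1), fit.candidates) for g in grid]
    )
    h = point_effect(fit, grid)
    draws = np.zeros((grid.size, n_draws))
    for l in np.flatnonzero(fit.active):
        slots = rng.choice(fit.pip.shape[1], size=n_draws, p=fit.pip[l])
        coefs = rng.normal(fit.mu[l, slots], fit.sigma[l, slots])
        draws += Fg[:, slots] * coefs[None, :]
    alpha = (1.0 - level) / 2.0
    lower = np.quantile(draws, alpha, axis=1)
    upper = np.quantile(draws, 1.0 - alpha, axis=1)
    if not fit.active.any():
        lower = np.zeros_like(h)
        upper = np.zeros_like(h)
    return EffectCurve(
        grid=grid, h=h, h_prime=None, lower=lower, upper=upper, band_kind="credible"
    )
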