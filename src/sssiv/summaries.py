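"""Per-stratum IV summary statistics and estimated weight functions.

For a stratum with data (Z, X, Y) the Wald ratio

    beta_hat = theta_hat / alpha_hat = Cov(Z, Y) / Cov(Z, X)

converges (under within-stratum exchangeability) to the weighted average
``integral of h'(x) W(x) dx`` of the effect intensity, where

    W(x) = Cov(Z, I{X >= x}) / Cov(Z, X)

is the stratum weight function.  W integrates to exactly 1 on any finite
sample (a telescoping identity: integrating the step function reproduces
Cov(Z, X - x_min) / Cov(Z, X)), is nonnegative under monotone instrument
effects, and equals the exposure density when (Z, X) are jointly normal.

This module computes the stratum-level quantities consumed by the
scalar-on-function / scalar-on-scalar models: alpha_hat, theta_hat, beta_hat,
its first- or second-order standard error, the exposure mean, and the exact
step-function representation of W.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import IVDataset
from .stratify import StratumAssignment

__all__ = [
    "WeightFunction",
    "StratumSummary",
    "wald_ratio",
    "standard_error",
    "estimate_weight_function",
    "parametric_weight_function",
    "summarize_strata",
    "linearity_q_test",
    "WeakStratumWarning",
]


class WeakStratumWarning(UserWarning):
    """Raised when stratum-level instrument strength is low (|t(alpha)| < 2)."""


# ---------------------------------------------------------------------------
# weight function
# ---------------------------------------------------------------------------


@dataclass
class WeightFunction:
    """Right-continuous step function on the exposure domain.

    ``breakpoints`` are J+1 strictly increasing exposure values; ``heights``
    holds the J step values, heights[j] applying on (breakpoints[j],
    breakpoints[j+1]].  All integrals and inner products against polynomials
    and indicator tails are computed exactly (piecewise closed form), never by
    Riemann sampling.
    """

    breakpoints: np.ndarray
    heights: np.ndarray

    def __post_init__(self) -> None:
        self.breakpoints = np.asarray(self.breakpoints, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        if self.breakpoints.size != self.heights.size + 1:
            raise ValueError("need len(breakpoints) == len(heights) + 1")
        if self.breakpoints.size >= 2 and np.any(np.diff(self.breakpoints) <= 0):
            raise ValueError("breakpoints must be strictly increasing")

    # -- basic geometry ----------------------------------------------------

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.breakpoints)

    @property
    def support(self) -> tuple[float, float]:
        return float(self.breakpoints[0]), float(self.breakpoints[-1])

    def __call__(self, x) -> np.ndarray:
        """Evaluate the step function (0 outside the support)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        idx = np.searchsorted(self.breakpoints, x, side="left") - 1
        out = np.zeros_like(x)
        inside = (x > self.breakpoints[0]) & (x <= self.breakpoints[-1])
        out[inside] = self.heights[idx[inside]]
        return out

    # -- exact integrals ----------------------------------------------------

    def integral(self) -> float:
        """Exact integral over the full support."""
        return float(self.heights @ self.widths)

    def tail_mass(self, t) -> np.ndarray | float:
        """Exact tail integral  int_t^inf W(x) dx  (vectorized in t)."""
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        b, h = self.breakpoints, self.heights
        # suffix[j] = integral over intervals j..J-1
        suffix = np.concatenate([np.cumsum((h * self.widths)[::-1])[::-1], [0.0]])
        idx = np.searchsorted(b, t_arr, side="left") - 1
        out = np.empty_like(t_arr)
        below = t_arr <= b[0]
        above = t_arr >= b[-1]
        mid = ~(below | above)
        out[below] = suffix[0]
        out[above] = 0.0
        j = idx[mid]
        out[mid] = h[j] * (b[j + 1] - t_arr[mid]) + suffix[j + 1]
        return out if np.ndim(t) else float(out[0])

    def moment(self, d: int) -> float:
        """Exact integral of x^d W(x) dx."""
        b = self.breakpoints
        return float(self.heights @ (b[1:] ** (d + 1) - b[:-1] ** (d + 1))) / (d + 1)

    def mean(self) -> float:
        return self.moment(1) / self.integral()

    def inner_poly(self, coeffs: np.ndarray) -> float:
        """Exact inner product with a polynomial sum_d coeffs[d] x^d."""
        return float(sum(c * self.moment(d) for d, c in enumerate(coeffs) if c != 0.0))

    def inner_quadrature(self, fn, order: int = 8) -> float:
        """Inner product with an arbitrary function by per-step Gauss-Legendre.

        Exact whenever ``fn`` is polynomial of degree <= 2*order - 1 on every
        step (e.g. B-splines whose knots are included in the breakpoints are
        handled by using enough nodes per step).
        """
        nodes, wts = np.polynomial.legendre.leggauss(order)
        a = self.breakpoints[:-1]
        half = self.widths / 2.0
        mid = (self.breakpoints[1:] + a) / 2.0
        xs = mid[:, None] + half[:, None] * nodes[None, :]
        vals = fn(xs.ravel()).reshape(xs.shape)
        return float(np.sum(self.heights * half * (vals @ wts)))

    # -- export --------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Two-column serialization (breakpoint, height); height[0] is NaN."""
        return pd.DataFrame(
            {
                "breakpoint": self.breakpoints,
                "height": np.concatenate([[np.nan], self.heights]),
            }
        )

    def to_grid(self, n: int = 512) -> pd.DataFrame:
        """Dense evaluation for plotting only (never used for integration)."""
        lo, hi = self.support
        xs = np.linspace(lo, hi, n)
        return pd.DataFrame({"x": xs, "w": self(xs)})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "WeightFunction":
        return cls(df["breakpoint"].to_numpy(float), df["height"].to_numpy(float)[1:])


# ---------------------------------------------------------------------------
# per-stratum estimates
# ---------------------------------------------------------------------------


@dataclass
class StratumSummary:
    """IV summary statistics of one stratum.

    ``alpha_hat`` and ``theta_hat`` are the slopes of the within-stratum
    simple regressions of X on Z and Y on Z (the Var(Z) scaling cancels in
    the Wald ratio, which equals Cov(Z,Y)/Cov(Z,X)); ``se_alpha``/``se_theta``
    are their classical standard errors.
    """

    k: int
    n_k: int
    alpha_hat: float
    theta_hat: float
    beta_hat: float
    se_beta: float
    xbar: float
    se_alpha: float = np.nan
    se_theta: float = np.nan
    weak: bool = False
    weight: WeightFunction | None = field(default=None, repr=False)


def _slope_and_se(z: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Slope and classical SE of the simple regression of w on z.

    Closed form for speed in the stratum loop; equivalent to
    scipy.stats.linregress (checked in the test suite).
    """
    n = z.size
    zc = z - z.mean()
    szz = float(zc @ zc)
    if szz == 0.0:
        raise ValueError("constant instrument within stratum")
    slope = float(zc @ w) / szz
    resid = w - w.mean() - slope * zc
    dof = n - 2
    se = np.sqrt(float(resid @ resid) / dof / szz) if dof > 0 else np.nan
    return slope, se


def wald_ratio(data_k: IVDataset) -> tuple[float, float, float]:
    """(alpha_hat, theta_hat, beta_hat) for one stratum.

    beta_hat = Cov(Z,Y)/Cov(Z,X) = theta_hat/alpha_hat; alpha/theta are
    returned on the slope scale (per unit Z).
    """
    if data_k.n < 3:
        raise ValueError("stratum needs at least 3 rows")
    z = data_k.z
    if np.unique(z).size < 2:
        raise ValueError("constant instrument within stratum")
    zc = z - z.mean()
    szz = float(zc @ zc)
    alpha = float(zc @ data_k.x) / szz
    theta = float(zc @ data_k.y) / szz
    if abs(alpha) < np.finfo(float).tiny * 1e4:
        raise ZeroDivisionError("instrument-exposure association is numerically zero")
    return alpha, theta, theta / alpha


def standard_error(summary: StratumSummary, order: str = "first") -> float:
    """First- or second-order delta-method SE of the Wald ratio.

    first:   se(theta_hat) / |alpha_hat|
    second:  sqrt(se(theta)^2/alpha^2 + (theta/alpha)^2 se(alpha)^2/alpha^2)
    """
    a, t = summary.alpha_hat, summary.theta_hat
    if a == 0:
        raise ZeroDivisionError("alpha_hat is zero")
    first = summary.se_theta / abs(a)
    if order == "first":
        return float(first)
    if order == "second":
        if not np.isfinite(summary.se_alpha):
            raise ValueError("second-order SE requires se(alpha_hat)")
        return float(np.sqrt(first**2 + (t / a) ** 2 * summary.se_alpha**2 / a**2))
    raise ValueError(f"unknown order {order!r}")


def estimate_weight_function(data_k: IVDataset) -> WeightFunction:
    """Nonparametric stratum weight Cov(Z, I{X>=x})/Cov(Z,X) as a step function.

    Breakpoints are the sorted distinct exposure values; on each interval
    (x_(j), x_(j+1)] the height is the sample covariance ratio, which makes
    the full integral exactly 1 by telescoping.
    """
    z, x = data_k.z, data_k.x
    order = np.argsort(x, kind="stable")
    xs, zs = x[order], z[order]
    zc_sum = zs - zs.mean()
    szx = float((xs - xs.mean()) @ zc_sum)
    if szx == 0.0:
        raise ZeroDivisionError("Cov(Z, X) is zero within stratum")
    # distinct breakpoints; for x in (x_(j), x_(j+1)] the indicator I{X >= x}
    # selects sorted positions with X > x_(j)
    distinct_mask = np.empty(xs.size, dtype=bool)
    distinct_mask[:-1] = xs[:-1] != xs[1:]
    distinct_mask[-1] = True
    breakpoints = xs[distinct_mask]
    if breakpoints.size < 2:
        raise ValueError("need at least 2 distinct exposure values in stratum")
    # suffix sums of centered Z over sorted positions
    suffix = np.concatenate([np.cumsum(zc_sum[::-1])[::-1], [0.0]])
    # position just after the last occurrence of each distinct value
    last_pos = np.flatnonzero(distinct_mask) + 1
    heights = suffix[last_pos[:-1]] / szx
    return WeightFunction(breakpoints=breakpoints, heights=heights)


def parametric_weight_function(
    xbar: float, s: float, n_steps: int = 2048, span: float = 6.0
) -> WeightFunction:
    """Normal-density weight (joint-normal (Z, X) case), discretized.

    Returns the N(xbar, s^2) density over xbar +/- span*s as a fine step
    function renormalized to integrate to exactly 1.
    """
    if s <= 0:
        raise ValueError("s must be positive")
    b = np.linspace(xbar - span * s, xbar + span * s, n_steps + 1)
    mid = (b[:-1] + b[1:]) / 2.0
    h = stats.norm.pdf(mid, loc=xbar, scale=s)
    wf = WeightFunction(breakpoints=b, heights=h)
    wf.heights = wf.heights / wf.integral()
    return wf


def summarize_strata(
    data: IVDataset,
    assignment: StratumAssignment,
    se_order: str = "first",
    weights: bool = True,
    drop_weak: bool = False,
    weak_t: float = 2.0,
) -> list[StratumSummary]:
    """Wald ratio, SE, exposure mean and weight function for every stratum.

    Strata with |alpha_hat| / se(alpha_hat) < ``weak_t`` are flagged weak; a
    single warning summarizes them.  They are retained unless ``drop_weak``.
    """
    out: list[StratumSummary] = []
    weak_ks: list[int] = []
    for k in range(1, assignment.K + 1):
        idx = assignment.indices(k)
        if idx.size == 0:
            raise ValueError(f"stratum {k} is empty")
        sub = data.subset(idx)
        alpha, se_a = _slope_and_se(sub.z, sub.x)
        theta, se_t = _slope_and_se(sub.z, sub.y)
        if alpha == 0.0:
            raise ZeroDivisionError(f"stratum {k}: instrument-exposure slope is zero")
        summ = StratumSummary(
            k=k,
            n_k=idx.size,
            alpha_hat=alpha,
            theta_hat=theta,
            beta_hat=theta / alpha,
            se_beta=np.nan,
            xbar=float(sub.x.mean()),
            se_alpha=se_a,
            se_theta=se_t,
        )
        summ.se_beta = standard_error(summ, order=se_order)
        if se_a > 0 and abs(alpha) / se_a < weak_t:
            summ.weak = True
            weak_ks.append(k)
        if weights:
            summ.weight = estimate_weight_function(sub)
        out.append(summ)
    if weak_ks:
        warnings.warn(
            f"{len(weak_ks)} of {assignment.K} strata have weak instrument "
            f"strength (|t| < {weak_t}): strata {weak_ks[:10]}"
            + ("..." if len(weak_ks) > 10 else ""),
            WeakStratumWarning,
            stacklevel=2,
        )
        if drop_weak:
            out = [s for s in out if not s.weak]
    return out


def summaries_frame(summaries: list[StratumSummary]) -> pd.DataFrame:
    """Tabular export of per-stratum summaries (strata_summary.csv layout)."""
    return pd.DataFrame(
        {
            "k": [s.k for s in summaries],
            "n_k": [s.n_k for s in summaries],
            "alpha_hat": [s.alpha_hat for s in summaries],
            "theta_hat": [s.theta_hat for s in summaries],
            "beta_hat": [s.beta_hat for s in summaries],
            "se_beta": [s.se_beta for s in summaries],
            "xbar": [s.xbar for s in summaries],
            "weak": [s.weak for s in summaries],
        }
    )


def linearity_q_test(summaries: list[StratumSummary]) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity test of the stratum Wald ratios.

    Under a constant effect intensity all strata estimate the same quantity;
    Q = sum_k (beta_k - beta_pooled)^2 / se_k^2 with the inverse-variance
    pooled estimate is referred to chi-square with K-1 degrees of freedom.
    Returns (Q, df, p).
    """
    if len(summaries) < 2:
        raise ValueError("need at least 2 strata")
    betas = np.array([s.beta_hat for s in summaries])
    ses = np.array([s.se_beta for s in summaries])
    if np.any(~np.isfinite(ses)) or np.any(ses <= 0):
        raise ValueError("all strata must have finite positive se_beta")
    w = 1.0 / ses**2
    pooled = float(w @ betas / w.sum())
    q = float(w @ (betas - pooled) ** 2)
    df = len(summaries) - 1
    p = float(stats.chi2.sf(q, df))
    return q, df, p
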