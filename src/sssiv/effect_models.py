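"""Scalar-on-function and scalar-on-scalar effect-shape regression.

Under a basis expansion h'(x) = sum_l b_l phi_l(x), the stratum Wald ratios
obey the linear model

    beta_k = sum_l b_l <phi_l, W_k> + eps_k,   eps_k ~ N(0, se_k^2),

a scalar-on-function (SoF) regression of the scalar stratum estimates on the
functional stratum weights.  The scalar-on-scalar (SoS) variant replaces the
exact inner products <phi_l, W_k> with phi_l evaluated at the stratum mean
exposure, which is accurate when strata are narrow but biased when h' jumps
inside a stratum.

Estimation is penalized weighted least squares with an optional roughness
penalty lambda * integral (D^m h')^2 and generalized cross-validation for
lambda; the closed form is b = (X' S^-1 X + lambda R)^-1 X' S^-1 beta.
Inner products against the step-function weights are computed exactly for
polynomial and indicator bases and by step-wise Gauss-Legendre quadrature
(exact at the spline degree) for B-splines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.interpolate import BSpline

from .curves import EffectCurve
from .summaries import StratumSummary, WeightFunction

__all__ = [
    "BasisSpec",
    "SoFFit",
    "build_sof_design",
    "fit_sof",
    "select_lambda_gcv",
    "fit_sos",
    "reconstruct_curve",
    "DEFAULT_LAMBDA_GRID",
]

DEFAULT_LAMBDA_GRID = np.logspace(-4, 4, 17)


# ---------------------------------------------------------------------------
# bases
# ---------------------------------------------------------------------------


@dataclass
class BasisSpec:
    """Basis for the effect intensity h'(x).

    family
        "polynomial" (phi_l = x^l, l = 0..degree),
        "changepoint_indicators" (constant plus I{x >= t_p} at ``candidates``),
        or "bspline" (degree ``degree``, interior ``knots``).
    """

    family: str
    degree: int = 2
    knots: np.ndarray | None = None
    candidates: np.ndarray | None = None
    strict: bool = False  # indicator evaluation I{x > t} instead of I{x >= t}

    def __post_init__(self) -> None:
        if self.family not in ("polynomial", "bspline", "changepoint_indicators"):
            raise ValueError(f"unknown basis family {self.family!r}")
        if self.family == "changepoint_indicators":
            if self.candidates is None:
                raise ValueError("changepoint_indicators needs candidates")
            self.candidates = np.sort(np.asarray(self.candidates, dtype=float))
        if self.family == "bspline":
            if self.knots is None:
                raise ValueError("bspline basis needs knots (including boundary)")
            self.knots = np.asarray(self.knots, dtype=float)
            if self.knots.size < 2:
                raise ValueError("need at least the two boundary knots")

    # -- size ----------------------------------------------------------------

    @property
    def n_basis(self) -> int:
        if self.family == "polynomial":
            return self.degree + 1
        if self.family == "changepoint_indicators":
            return self.candidates.size + 1
        return self.knots.size - 2 + self.degree + 1  # interior + degree + 1

    def _full_knots(self) -> np.ndarray:
        k = self.degree
        return np.concatenate(
            [np.repeat(self.knots[0], k), self.knots, np.repeat(self.knots[-1], k)]
        )

    @property
    def support(self) -> tuple[float, float]:
        """Domain over which the basis is defined (inf for unbounded families)."""
        if self.family == "bspline":
            return float(self.knots[0]), float(self.knots[-1])
        return -np.inf, np.inf

    # -- evaluation ----------------------------------------------------------

    def evaluate(self, x) -> np.ndarray:
        """Matrix of phi_l(x), shape (len(x), L)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if self.family == "polynomial":
            return np.vander(x, self.degree + 1, increasing=True)
        if self.family == "changepoint_indicators":
            # strictness only matters at the threshold itself (measure zero
            # for the integrals; relevant when evaluating h' at a threshold)
            cols = [np.ones_like(x)] + [
                ((x > t) if self.strict else (x >= t)).astype(float)
                for t in self.candidates
            ]
            return np.column_stack(cols)
        t = self._full_knots()
        return BSpline.design_matrix(
            np.clip(x, t[0], t[-1]), t, self.degree
        ).toarray()

    def antiderivative0(self, x) -> np.ndarray:
        """Matrix of int_0^x phi_l(s) ds, shape (len(x), L)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if self.family == "polynomial":
            powers = np.arange(1, self.degree + 2)
            return x[:, None] ** powers[None, :] / powers[None, :]
        if self.family == "changepoint_indicators":
            cols = [x] + [
                np.maximum(x - t, 0.0) - max(-t, 0.0) for t in self.candidates
            ]
            return np.column_stack(cols)
        t = self._full_knots()
        L = self.n_basis
        out = np.empty((x.size, L))
        xc = np.clip(x, t[0], t[-1])
        zero = np.clip(0.0, t[0], t[-1])
        for l in range(L):
            c = np.zeros(L)
            c[l] = 1.0
            anti = BSpline(t, c, self.degree, extrapolate=False).antiderivative()
            out[:, l] = anti(xc) - anti(zero)
        return out

    # -- inner products and penalty -------------------------------------------

    def inner_with_weight(self, wf: WeightFunction) -> np.ndarray:
        """Exact inner products <phi_l, W>, shape (L,)."""
        if self.family == "polynomial":
            return np.array([wf.moment(d) for d in range(self.degree + 1)])
        if self.family == "changepoint_indicators":
            tails = np.atleast_1d(wf.tail_mass(self.candidates))
            return np.concatenate([[wf.integral()], tails])
        lo, hi = self.support
        s_lo, s_hi = wf.support
        if s_lo < lo - 1e-12 or s_hi > hi + 1e-12:
            raise ValueError("basis support does not cover the weight support")
        # per-step Gauss-Legendre, exact for the spline degree
        order = self.degree // 2 + 1
        t = self._full_knots()
        L = self.n_basis
        vals = np.empty(L)
        for l in range(L):
            c = np.zeros(L)
            c[l] = 1.0
            spl = BSpline(t, c, self.degree, extrapolate=False)
            vals[l] = wf.inner_quadrature(
                lambda s: np.nan_to_num(spl(s)), order=max(order, 2)
            )
        return vals

    def penalty(self, m: int, domain: tuple[float, float]) -> np.ndarray:
        """Roughness penalty matrix R_ij = <D^m phi_i, D^m phi_j> over ``domain``.

        For the change-point family the indicator derivatives are point
        masses, so no quadratic roughness penalty applies; R is zero (use
        lambda = 0 with this basis).
        """
        L = self.n_basis
        if self.family == "changepoint_indicators":
            return np.zeros((L, L))
        a, b = domain
        if self.family == "polynomial":
            R = np.zeros((L, L))
            for i in range(m, L):
                ci = np.prod(np.arange(i - m + 1, i + 1, dtype=float))
                for j in range(m, L):
                    cj = np.prod(np.arange(j - m + 1, j + 1, dtype=float))
                    p = i + j - 2 * m
                    R[i, j] = ci * cj * (b ** (p + 1) - a ** (p + 1)) / (p + 1)
            return R
        # B-splines: D^m of each element is piecewise polynomial of degree
        # degree - m; Gauss-Legendre on each knot span is exact
        t = self._full_knots()
        spans = np.unique(np.clip(t, a, b))
        if spans.size < 2:
            return np.zeros((L, L))
        order = max(self.degree - m, 0) + 1
        nodes, wts = np.polynomial.legendre.leggauss(order)
        half = np.diff(spans) / 2.0
        mid = (spans[:-1] + spans[1:]) / 2.0
        xs = (mid[:, None] + half[:, None] * nodes[None, :]).ravel()
        quad_w = (half[:, None] * np.broadcast_to(wts, (half.size, wts.size))).ravel()
        D = np.empty((xs.size, L))
        for l in range(L):
            c = np.zeros(L)
            c[l] = 1.0
            spl = BSpline(t, c, self.degree, extrapolate=False)
            dl = spl.derivative(m) if m > 0 else spl
            D[:, l] = np.nan_to_num(dl(xs))
        return (D * quad_w[:, None]).T @ D


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class SoFFit:
    """Design, penalty and (once fitted) coefficients of an SoF/SoS model."""

    design: np.ndarray                 # K x L, entries <phi_l, W_k> (or phi_l(xbar_k))
    sigma2: np.ndarray                 # K, diagonal of Sigma (se_beta^2)
    response: np.ndarray               # K, stratum Wald ratios
    basis: BasisSpec
    domain: tuple[float, float]
    kind: str = "sof"
    b_hat: np.ndarray | None = None
    cov_b: np.ndarray | None = None
    lam: float = 0.0
    m: int = 2
    R: np.ndarray | None = field(default=None, repr=False)

    @property
    def K(self) -> int:
        return self.design.shape[0]

    @property
    def L(self) -> int:
        return self.design.shape[1]


def _skeleton_from(
    summaries: list[StratumSummary], basis: BasisSpec, kind: str
) -> SoFFit:
    response = np.array([s.beta_hat for s in summaries])
    sigma2 = np.array([s.se_beta**2 for s in summaries])
    if np.any(~np.isfinite(sigma2)) or np.any(sigma2 <= 0):
        raise ValueError("all strata need finite positive se_beta")
    if kind == "sof":
        lo_hi = []
        rows = []
        for s in summaries:
            if s.weight is None:
                raise ValueError(f"stratum {s.k} has no weight function")
            b_lo, b_hi = basis.support
            w_lo, w_hi = s.weight.support
            if w_lo < b_lo - 1e-12 or w_hi > b_hi + 1e-12:
                raise ValueError(
                    f"basis support does not cover the weight support of stratum {s.k}"
                )
            rows.append(basis.inner_with_weight(s.weight))
            lo_hi.append(s.weight.support)
        design = np.vstack(rows)
        domain = (min(lo for lo, _ in lo_hi), max(hi for _, hi in lo_hi))
    else:
        xbar = np.array([s.xbar for s in summaries])
        design = basis.evaluate(xbar)
        domain = (float(xbar.min()), float(xbar.max()))
    return SoFFit(
        design=design,
        sigma2=sigma2,
        response=response,
        basis=basis,
        domain=domain,
        kind=kind,
    )


def build_sof_design(summaries: list[StratumSummary], basis: BasisSpec) -> SoFFit:
    """SoF design with exact inner products of the basis against each weight."""
    return _skeleton_from(summaries, basis, "sof")


def build_sos_design(summaries: list[StratumSummary], basis: BasisSpec) -> SoFFit:
    """SoS design A_{k,l} = phi_l(xbar_k) (narrow-stratum approximation)."""
    return _skeleton_from(summaries, basis, "sos")


def fit_sof(skeleton: SoFFit, lam: float = 0.0, m: int = 2) -> SoFFit:
    """Closed-form penalized GLS: b = (X'S^-1X + lam R)^-1 X'S^-1 beta.

    ``cov_b`` is the sandwich (X'S^-1X + lam R)^-1 X'S^-1X (X'S^-1X + lam R)^-1,
    exact under eps_k ~ N(0, se_k^2).
    """
    X = skeleton.design
    w = 1.0 / skeleton.sigma2
    XtWX = (X * w[:, None]).T @ X
    XtWy = (X * w[:, None]).T @ skeleton.response
    R = skeleton.basis.penalty(m, skeleton.domain)
    A = XtWX + lam * R
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular normal equations; add a roughness penalty (lambda > 0) "
            "or reduce the number of basis functions"
        ) from err
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            "ill-conditioned normal equations; add a roughness penalty "
            "(lambda > 0) or reduce the number of basis functions"
        )
    b = Ainv @ XtWy
    cov = Ainv @ XtWX @ Ainv
    return SoFFit(
        design=X,
        sigma2=skeleton.sigma2,
        response=skeleton.response,
        basis=skeleton.basis,
        domain=skeleton.domain,
        kind=skeleton.kind,
        b_hat=b,
        cov_b=cov,
        lam=float(lam),
        m=m,
        R=R,
    )


def select_lambda_gcv(
    skeleton: SoFFit, m: int = 2, lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID
) -> float:
    """Generalized cross-validation on the whitened system.

    GCV(lam) = (K / (K - tr H)) * (SSE / (K - tr H)) with the hat matrix
    H = S^-1/2 X (X'S^-1X + lam R)^-1 X'S^-1/2 and SSE the whitened residual
    sum of squares.  Returns the grid value minimizing GCV; grid points with
    tr(H) >= K are skipped with a warning.
    """
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if lambda_grid.size == 0 or np.any(lambda_grid < 0):
        raise ValueError("lambda grid must be nonempty and nonnegative")
    X = skeleton.design
    K = skeleton.K
    s = np.sqrt(skeleton.sigma2)
    Xw = X / s[:, None]
    yw = skeleton.response / s
    XtWX = Xw.T @ Xw
    R = skeleton.basis.penalty(m, skeleton.domain)
    best_lam, best_gcv = None, np.inf
    for lam in lambda_grid:
        try:
            Ainv = np.linalg.inv(XtWX + lam * R)
        except np.linalg.LinAlgError:
            warnings.warn(f"lambda={lam:g}: singular system, skipped", stacklevel=2)
            continue
        H = Xw @ Ainv @ Xw.T
        tr = float(np.trace(H))
        if tr >= K:
            warnings.warn(
                f"lambda={lam:g}: tr(H)={tr:.2f} >= K={K}, skipped", stacklevel=2
            )
            continue
        resid = yw - H @ yw
        sse = float(resid @ resid)
        gcv = (K / (K - tr)) * (sse / (K - tr))
        if gcv < best_gcv:
            best_gcv, best_lam = gcv, float(lam)
    if best_lam is None:
        raise ValueError("no admissible lambda in the grid")
    return best_lam


def fit_sos(
    summaries: list[StratumSummary],
    basis: BasisSpec,
    lam: float = 0.0,
    m: int = 2,
) -> SoFFit:
    """Scalar-on-scalar fit: identical algebra with design A_{k,l} = phi_l(xbar_k)."""
    return fit_sof(build_sos_design(summaries, basis), lam=lam, m=m)


def reconstruct_curve(
    fit: SoFFit, grid: np.ndarray, level: float = 0.95
) -> EffectCurve:
    """Effect curve h(x) = [int_0^x phi]' b (anchored h(0)=0) with Wald band.

    The pointwise band is the delta-method interval on the linear functional
    h(x) = Phi(x)' b using ``cov_b``; no simultaneous adjustment.
    """
    if fit.b_hat is None:
        raise ValueError("fit the model before reconstructing the curve")
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    Phi_d = fit.basis.evaluate(grid)
    Phi = fit.basis.antiderivative0(grid)
    h = Phi @ fit.b_hat
    hp = Phi_d @ fit.b_hat
    var_h = np.einsum("ij,jk,ik->i", Phi, fit.cov_b, Phi)
    se_h = np.sqrt(np.maximum(var_h, 0.0))
    zcrit = stats.norm.ppf(0.5 + level / 2.0)
    return EffectCurve(
        grid=grid,
        h=h,
        h_prime=hp,
        lower=h - zcrit * se_h,
        upper=h + zcrit * se_h,
        band_kind="confidence",
    )
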