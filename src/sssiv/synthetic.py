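"""Simulation generators and closed-form comparator estimators.

Three families of structural models are implemented (Parts I-III), all built
around a deliberately weak instrument (exposure variance explained ~0.003 for
a binary instrument, ~0.01 for a standard-normal one — the regime typical of
Mendelian randomization):

Part I   X = 0.15 Z + U + eps_X with a linear outcome effect h(x) = x and
         four (instrument, confounding) scenarios: Z binary or N(0,1),
         confounding simple (Y = X + U + eps_Y) or complex
         (Y = X + |U| + eps_X^2 + 2|U||eps_X| + eps_Y).
Part II  Binary instrument, same exposure model, two effect shapes:
         h(x) = x + 0.5 x^2 (smooth) and h(x) = (x)_+ (one jump in h').
Part III Four instrument-exposure models (binary/normal instrument crossed
         with normal/lognormal exposure) x four effect shapes (linear, one
         change-point, two change-points, quadratic), Y = h(X) + U + eps_Y.

All generators are deterministic given (spec, seed).  The module also houses
the theoretical exposure laws implied by each scenario (used to evaluate
estimates at exact population quantiles) and two oracle comparators: the
control-function method and the exactly-identified two-parameter IV
regression, both assuming the true quadratic effect basis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, stats

from .curves import EffectCurve
from .dataset import IVDataset

__all__ = [
    "ScenarioSpec",
    "GeneratedDataset",
    "TrueEffect",
    "FitFailure",
    "generate",
    "exposure_law",
    "oracle_control_function",
    "oracle_iv_regression",
    "quadratic_curve",
    "instrument_r_squared",
    "write_dataset",
]

PART_II_CASES = ("linear_quadratic", "jump")


class FitFailure(RuntimeError):
    """An estimator's linear system was singular; counts as a failed replicate."""


# ---------------------------------------------------------------------------
# scenario specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the simulation design.

    part
        "I", "II" or "III".
    scenario
        1-4 for Parts I and III (instrument/confounding or instrument/exposure
        model); must be None for Part II.
    effect_case
        None for Part I; "linear_quadratic" or "jump" for Part II; 1-4 for
        Part III.
    """

    part: str
    n: int
    seed: int
    scenario: int | None = None
    effect_case: int | str | None = None

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        grid = (
            "valid: Part I scenario 1-4 (no effect_case); "
            "Part II effect_case in {'linear_quadratic','jump'} (no scenario); "
            "Part III scenario 1-4 x effect_case 1-4"
        )
        if self.part == "I":
            if self.scenario not in (1, 2, 3, 4) or self.effect_case is not None:
                raise ValueError(f"bad Part I spec {self}; {grid}")
        elif self.part == "II":
            if self.scenario is not None or self.effect_case not in PART_II_CASES:
                raise ValueError(f"bad Part II spec {self}; {grid}")
        elif self.part == "III":
            if self.scenario not in (1, 2, 3, 4) or self.effect_case not in (1, 2, 3, 4):
                raise ValueError(f"bad Part III spec {self}; {grid}")
        else:
            raise ValueError(f"unknown part {self.part!r}; {grid}")

    def to_dict(self) -> dict:
        return {
            "part": self.part,
            "scenario": self.scenario,
            "effect_case": self.effect_case,
            "n": self.n,
            "seed": self.seed,
        }


@dataclass
class TrueEffect:
    """True effect shape h (anchored h(0)=0), its derivative, change-points."""

    h: Callable[[np.ndarray], np.ndarray]
    h_prime: Callable[[np.ndarray], np.ndarray]
    changepoints: list[float] = field(default_factory=list)


@dataclass
class GeneratedDataset:
    data: IVDataset
    true_effect: TrueEffect
    spec: ScenarioSpec

    @property
    def true_changepoints(self) -> list[float]:
        return self.true_effect.changepoints


# ---------------------------------------------------------------------------
# effect shapes
# ---------------------------------------------------------------------------


def _ramp(t: float) -> Callable[[np.ndarray], np.ndarray]:
    return lambda x: np.maximum(np.asarray(x, dtype=float) - t, 0.0)


def _step(t: float) -> Callable[[np.ndarray], np.ndarray]:
    return lambda x: (np.asarray(x, dtype=float) >= t).astype(float)


def _linear_effect() -> TrueEffect:
    return TrueEffect(
        h=lambda x: np.asarray(x, dtype=float),
        h_prime=lambda x: np.ones_like(np.asarray(x, dtype=float)),
        changepoints=[],
    )


def _part_ii_effect(case: str) -> TrueEffect:
    if case == "linear_quadratic":
        # benchmark definition: the outcome generator uses h(X) = X + 0.5 X^2
        # while estimated intensities are scored against the design's
        # reference intensity 1 + 2x
        return TrueEffect(
            h=lambda x: np.asarray(x) + 0.5 * np.asarray(x) ** 2,
            h_prime=lambda x: 1.0 + 2.0 * np.asarray(x, dtype=float),
            changepoints=[],
        )
    # one jump in the intensity: h(x) = (x)_+ so h'(x) = I{x > 0} (strict)
    return TrueEffect(
        h=_ramp(0.0),
        h_prime=lambda x: (np.asarray(x, dtype=float) > 0.0).astype(float),
        changepoints=[0.0],
    )


def _part_iii_effect(scenario: int, case: int) -> TrueEffect:
    normal_exposure = scenario in (1, 2)
    if case == 1:
        return _linear_effect()
    if case == 2:
        t = 0.0 if normal_exposure else 2.5
        return TrueEffect(h=_ramp(t), h_prime=_step(t), changepoints=[t])
    if case == 3:
        if normal_exposure:
            # h(x) = 0.5 x + 0.5 (x + 0.5)_+ - 0.25 + 0.5 (x - 0.5)_+
            r1, r2 = _ramp(-0.5), _ramp(0.5)
            return TrueEffect(
                h=lambda x: 0.5 * np.asarray(x) + 0.5 * r1(x) - 0.25 + 0.5 * r2(x),
                h_prime=lambda x: 0.5
                + 0.5 * _step(-0.5)(x)
                + 0.5 * _step(0.5)(x),
                changepoints=[-0.5, 0.5],
            )
        r1, r2 = _ramp(0.5), _ramp(2.5)
        return TrueEffect(
            h=lambda x: 0.5 * np.asarray(x) + 0.5 * r1(x) + 0.5 * r2(x),
            h_prime=lambda x: 0.5 + 0.5 * _step(0.5)(x) + 0.5 * _step(2.5)(x),
            changepoints=[0.5, 2.5],
        )
    # case 4: smooth quadratic (no change-points; stresses the change-point model)
    a = -1.0 if normal_exposure else -2.0
    return TrueEffect(
        h=lambda x: a * np.asarray(x) + 0.5 * np.asarray(x) ** 2,
        h_prime=lambda x: a + np.asarray(x, dtype=float),
        changepoints=[],
    )


def true_effect_for(spec: ScenarioSpec) -> TrueEffect:
    if spec.part == "I":
        return _linear_effect()
    if spec.part == "II":
        return _part_ii_effect(spec.effect_case)
    return _part_iii_effect(spec.scenario, spec.effect_case)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _draw_instrument(rng: np.random.Generator, binary: bool, n: int) -> np.ndarray:
    if binary:
        return rng.binomial(1, 0.5, size=n) - 0.5
    return rng.standard_normal(n)


def generate(spec: ScenarioSpec) -> GeneratedDataset:
    """Draw one dataset from the structural model selected by ``spec``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    effect = true_effect_for(spec)

    if spec.part in ("I", "II"):
        binary = spec.part == "II" or spec.scenario in (1, 2)
    else:
        binary = spec.scenario in (1, 3)
    z = _draw_instrument(rng, binary, n)
    u = rng.standard_normal(n)
    eps_x = rng.standard_normal(n)
    eps_y = rng.standard_normal(n)

    if spec.part == "III" and spec.scenario in (3, 4):
        x = np.exp(0.3 * z + u + eps_x)
    else:
        x = 0.15 * z + u + eps_x

    if spec.part == "I" and spec.scenario in (2, 4):
        # complex confounding: the confounder's effect on the outcome is not
        # expressible through its effect on the exposure
        conf = np.abs(u) + eps_x**2 + 2.0 * np.abs(u) * np.abs(eps_x)
    else:
        conf = u
    y = effect.h(x) + conf + eps_y

    data = IVDataset(z=z, x=x, y=y, u=u)
    return GeneratedDataset(data=data, true_effect=effect, spec=spec)


def write_dataset(gd: GeneratedDataset, path) -> None:
    """CSV `id,Z,X,Y` plus a JSON sidecar with spec, seed and change-points."""
    path = Path(path)
    gd.data.to_csv(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {"spec": gd.spec.to_dict(), "true_changepoints": gd.true_changepoints},
            indent=2,
        )
    )


# ---------------------------------------------------------------------------
# theoretical exposure laws
# ---------------------------------------------------------------------------


class NormalLaw:
    def __init__(self, mu: float, sigma: float):
        self.mu, self.sigma = mu, sigma

    def cdf(self, x):
        return stats.norm.cdf(x, self.mu, self.sigma)

    def quantile(self, p):
        return stats.norm.ppf(p, self.mu, self.sigma)


class NormalMixtureLaw:
    """Equal-weight two-component normal mixture (binary instrument)."""

    def __init__(self, means: Sequence[float], sigma: float):
        self.means = np.asarray(means, dtype=float)
        self.sigma = sigma

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        return np.mean(
            [stats.norm.cdf(x, m, self.sigma) for m in self.means], axis=0
        )

    def quantile(self, p):
        p_arr = np.atleast_1d(np.asarray(p, dtype=float))
        lo = self.means.min() - 10 * self.sigma
        hi = self.means.max() + 10 * self.sigma
        out = np.array(
            [optimize.brentq(lambda x: self.cdf(x) - pi, lo, hi) for pi in p_arr]
        )
        return out if np.ndim(p) else float(out[0])


class ExpOfLaw:
    """Law of exp(W) for W following a base law (lognormal-type exposures)."""

    def __init__(self, base):
        self.base = base

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        pos = x > 0
        out[pos] = self.base.cdf(np.log(x[pos]))
        return out

    def quantile(self, p):
        return np.exp(self.base.quantile(p))


def exposure_law(spec: ScenarioSpec):
    """Closed-form exposure distribution implied by the scenario.

    Linear exposure models: X = 0.15 Z + U + eps_X with U, eps_X ~ N(0,1),
    hence N(0, 2 + 0.0225) for a standard-normal instrument, or an
    equal-weight mixture of N(+/-0.075, 2) for the centered binary one.
    Lognormal models exponentiate 0.3 Z + U + eps_X analogously.
    """
    sqrt2 = np.sqrt(2.0)
    if spec.part in ("I", "II"):
        binary = spec.part == "II" or spec.scenario in (1, 2)
        if binary:
            return NormalMixtureLaw([-0.075, 0.075], sqrt2)
        return NormalLaw(0.0, np.sqrt(2.0 + 0.15**2))
    if spec.scenario == 1:
        return NormalMixtureLaw([-0.075, 0.075], sqrt2)
    if spec.scenario == 2:
        return NormalLaw(0.0, np.sqrt(2.0 + 0.15**2))
    if spec.scenario == 3:
        return ExpOfLaw(NormalMixtureLaw([-0.15, 0.15], sqrt2))
    return ExpOfLaw(NormalLaw(0.0, np.sqrt(2.0 + 0.3**2)))


def instrument_r_squared(data: IVDataset) -> float:
    """Coefficient of determination from regressing X on Z."""
    zc = data.z - data.z.mean()
    xc = data.x - data.x.mean()
    denom = float(zc @ zc) * float(xc @ xc)
    if denom == 0.0:
        raise ValueError("degenerate Z or X")
    return float(zc @ xc) ** 2 / denom


# ---------------------------------------------------------------------------
# oracle comparators (quadratic effect basis h(x) = b1 x + b2 x^2)
# ---------------------------------------------------------------------------


def quadratic_curve(beta1: float, beta2: float, grid: np.ndarray) -> EffectCurve:
    g = np.asarray(grid, dtype=float)
    return EffectCurve(
        grid=g,
        h=beta1 * g + beta2 * g**2,
        h_prime=beta1 + 2.0 * beta2 * g,
    )


def oracle_control_function(data: IVDataset, grid: np.ndarray) -> EffectCurve:
    """Two-step control-function fit with the oracle quadratic basis.

    Stage 1: residual r from the OLS of X on Z.  Stage 2: OLS of Y on
    {1, X, X^2, r}; the X and X^2 coefficients give h(x) = b1 x + b2 x^2.
    """
    if np.unique(data.x).size < 3:
        raise FitFailure("need at least 3 distinct exposure values")
    z, x, y = data.z, data.x, data.y
    zc = z - z.mean()
    szz = float(zc @ zc)
    if szz == 0.0:
        raise FitFailure("constant instrument")
    slope = float(zc @ x) / szz
    r = x - x.mean() - slope * zc
    design = np.column_stack([np.ones_like(x), x, x**2, r])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        raise FitFailure("singular second-stage design")
    return quadratic_curve(float(coef[1]), float(coef[2]), grid)


def oracle_iv_regression(data: IVDataset, grid: np.ndarray) -> EffectCurve:
    """Exactly-identified two-parameter IV regression.

    The instrument is dichotomized (its two levels if binary, else a split at
    the empirical median) and the 2x2 conditional-moment system

        E(Y | z*) = b1 E(X | z*) + b2 E(X^2 | z*),  z* in {0, 1}

    is solved for (b1, b2).
    """
    z, x, y = data.z, data.x, data.y
    levels = np.unique(z)
    if levels.size < 2:
        raise FitFailure("constant instrument")
    if levels.size == 2:
        arm = z == levels[1]
    else:
        arm = z > np.median(z)
    if arm.all() or (~arm).all():
        raise FitFailure("degenerate instrument split")
    m = np.array(
        [
            [x[~arm].mean(), (x[~arm] ** 2).mean()],
            [x[arm].mean(), (x[arm] ** 2).mean()],
        ]
    )
    rhs = np.array([y[~arm].mean(), y[arm].mean()])
    det = m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
    scale = np.abs(m).max()
    if not np.isfinite(det) or abs(det) < 1e-12 * max(scale**2, 1.0):
        raise FitFailure("singular 2x2 moment matrix")
    beta1 = (m[1, 1] * rhs[0] - m[0, 1] * rhs[1]) / det
    beta2 = (-m[1, 0] * rhs[0] + m[0, 0] * rhs[1]) / det
    return quadratic_curve(float(beta1), float(beta2), grid)
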