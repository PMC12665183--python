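"""Effect-curve container shared by the frequentist and Bayesian fitters."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["EffectCurve"]


@dataclass
class EffectCurve:
    """Estimated effect shape h(x) (and intensity h'(x)) on an exposure grid.

    The effect shape is anchored at h(0) = 0: h(x) is the average causal
    contrast of moving the exposure from the reference level 0 to x.

    Attributes
    ----------
    grid
        Exposure values at which the curve is evaluated.
    h
        Point estimate of the effect shape (outcome units).
    h_prime
        Point estimate of the effect intensity h'(x) (outcome per exposure
        unit); may be NaN where undefined.
    lower, upper
        Pointwise 95% band; NaN where no uncertainty is available.
    band_kind
        "confidence" (frequentist, Wald) or "credible" (posterior).
    """

    grid: np.ndarray
    h: np.ndarray
    h_prime: np.ndarray | None = None
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None
    band_kind: str = "confidence"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.h = np.asarray(self.h, dtype=float)
        n = self.grid.size
        if self.h_prime is None:
            self.h_prime = np.full(n, np.nan)
        if self.lower is None:
            self.lower = np.full(n, np.nan)
        if self.upper is None:
            self.upper = np.full(n, np.nan)
        self.h_prime = np.asarray(self.h_prime, dtype=float)
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "grid": self.grid,
                "h": self.h,
                "h_prime": self.h_prime,
                "lower": self.lower,
                "upper": self.upper,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)
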