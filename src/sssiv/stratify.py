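"""Collider-robust stratification of an IV sample.

Both methods target selection on the *counterfactual* exposure X(z) rather
than the observed exposure X.  Because X is a common effect of the instrument
and the confounders, stratifying directly on X induces collider bias (the
instrument becomes associated with the confounders inside each stratum);
stratifying on X(z) does not, while still producing strata with distinct
exposure distributions.

Two implementations are provided:

* :func:`residual_stratify` (prediction method) — assumes a structural
  exposure model X = t(f(Z) + g_X(U, eps)); the predicted counterfactual
  exposure at a reference instrument level is the (transformed) residual of
  X on Z, and strata are its quantile groups.
* :func:`doubly_ranked_stratify` (matching method) — assumes only rank
  preservation of the counterfactual exposure across instrument levels; rows
  are sorted by Z into pre-strata of size K, and the k-th smallest exposure
  in each pre-stratum goes to stratum k.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dataset import IVDataset

logger = logging.getLogger(__name__)

__all__ = ["StratumAssignment", "residual_stratify", "doubly_ranked_stratify", "naive_stratify"]


@dataclass
class StratumAssignment:
    """Partition of the retained rows into K strata.

    ``labels`` holds a stratum index in 1..K for retained rows and 0 for rows
    dropped for divisibility (doubly-ranked only). ``dropped`` counts those
    excluded rows.
    """

    method: str
    K: int
    labels: np.ndarray
    dropped: int = 0

    def indices(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.labels == k)

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.K + 1)[1:]


def _quantile_groups(values: np.ndarray, K: int) -> np.ndarray:
    """Assign 1..K by sorted rank, equal-size groups, remainder to low strata.

    Ties broken by original row order (stable sort).
    """
    n = values.size
    base, rem = divmod(n, K)
    # group sizes: first `rem` strata get one extra member
    sizes = np.full(K, base, dtype=int)
    sizes[:rem] += 1
    edges = np.concatenate([[0], np.cumsum(sizes)])
    order = np.argsort(values, kind="stable")
    labels = np.empty(n, dtype=int)
    for k in range(K):
        labels[order[edges[k] : edges[k + 1]]] = k + 1
    return labels


def residual_stratify(
    data: IVDataset, K: int, transform: str = "identity"
) -> StratumAssignment:
    """Prediction-method stratification via the instrument-exposure residual.

    Fits the linear instrument-exposure model t^{-1}(X) = a + b Z + error by
    least squares, predicts each individual's counterfactual exposure at the
    reference instrument level z0 = 0 as
    ``X_hat(0) = t(a + t^{-1}(X) - a - b Z) = t(t^{-1}(X) - b Z)``,
    and assigns strata as equal-size quantile groups of X_hat(0).

    Parameters
    ----------
    transform
        "identity" or "log"; the known monotone transform t of the structural
        exposure model (log requires all X > 0).
    """
    if K < 2:
        raise ValueError("K must be at least 2")
    if K > data.n // 2:
        raise ValueError(f"K={K} exceeds n/2={data.n // 2}")
    if transform == "identity":
        tx = data.x
    elif transform == "log":
        if np.any(data.x <= 0):
            raise ValueError("log transform requires all exposures > 0")
        tx = np.log(data.x)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    z = data.z
    zc = z - z.mean()
    denom = float(zc @ zc)
    cov_zx = float(zc @ (tx - tx.mean()))
    if denom == 0.0 or abs(cov_zx) < 1e-12 * max(1.0, float(np.std(tx)) * np.sqrt(denom)):
        raise ValueError("instrument unassociated with exposure")
    slope = cov_zx / denom
    # only the ordering of X_hat(0) matters for quantile grouping; the
    # monotone transform t preserves it, so rank on t^{-1}-scale directly
    counterfactual = tx - slope * z
    labels = _quantile_groups(counterfactual, K)
    return StratumAssignment(method="residual", K=K, labels=labels, dropped=0)


def doubly_ranked_stratify(data: IVDataset, K: int) -> StratumAssignment:
    """Matching-method (doubly-ranked) stratification.

    Rows are stably sorted by instrument value and cut into floor(n/K)
    pre-strata of exactly K consecutive rows (trailing remainder rows are
    dropped and counted).  Within each pre-stratum the exposures are ranked;
    stratum k collects the rank-k individual from every pre-stratum, so each
    stratum has one member per complete pre-stratum and the stratum exposure
    means are increasing in k.
    """
    if K < 2:
        raise ValueError("K must be at least 2")
    n = data.n
    if n < K:
        raise ValueError(f"need n >= K (got n={n}, K={K})")
    n_pre = n // K
    n_keep = n_pre * K
    dropped = n - n_keep
    if dropped:
        logger.info("doubly-ranked: dropping %d trailing rows (n mod K)", dropped)
    z_order = np.argsort(data.z, kind="stable")[:n_keep]
    labels = np.zeros(n, dtype=int)
    x_kept = data.x[z_order].reshape(n_pre, K)
    # rank X within each pre-stratum, ties broken by original row order
    # (stable argsort within rows of the Z-sorted layout)
    ranks = np.argsort(np.argsort(x_kept, axis=1, kind="stable"), axis=1, kind="stable")
    labels[z_order] = ranks.ravel() + 1
    return StratumAssignment(method="doubly_ranked", K=K, labels=labels, dropped=dropped)


def naive_stratify(data: IVDataset, K: int) -> StratumAssignment:
    """Stratify directly on the observed exposure (collider-biased baseline).

    Provided only as a diagnostic contrast: conditioning on the observed
    exposure opens the collider path Z -> X <- U, so within-stratum
    exchangeability fails.  Never use for analysis.
    """
    if K < 2:
        raise ValueError("K must be at least 2")
    labels = _quantile_groups(data.x, K)
    return StratumAssignment(method="naive_exposure", K=K, labels=labels, dropped=0)
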