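"""Individual-level instrument/exposure/outcome data.

The whole framework operates on triples (Z, X, Y): a single (possibly binary,
score-valued, or continuous) instrument Z, a continuous exposure X, and a
continuous outcome Y.  Synthetic datasets may additionally carry the simulated
confounder U, which is never used by the estimators but is convenient for
exchangeability diagnostics in tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["IVDataset"]


@dataclass
class IVDataset:
    """Per-individual records (Z, X, Y).

    Parameters
    ----------
    z, x, y
        Instrument, exposure and outcome values, one entry per individual.
    ids
        Opaque row identifiers; defaults to 0..n-1.
    u
        Optional simulated confounder (diagnostics only).
    extra
        Optional extra columns, preserved through I/O untouched.
    """

    z: np.ndarray
    x: np.ndarray
    y: np.ndarray
    ids: np.ndarray | None = None
    u: np.ndarray | None = None
    extra: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = self.z.size
        if self.x.size != n or self.y.size != n:
            raise ValueError("Z, X, Y must have equal length")
        if self.ids is None:
            self.ids = np.arange(n)
        self.ids = np.asarray(self.ids)
        if self.u is not None:
            self.u = np.asarray(self.u, dtype=float)

    @property
    def n(self) -> int:
        return self.z.size

    def validate(self, min_distinct_x: int = 2) -> "IVDataset":
        """Check the ingestion invariants (no NaNs, enough distinct values)."""
        if np.unique(self.z).size < 2:
            raise ValueError("instrument Z must take at least 2 distinct values")
        if np.unique(self.x).size < min_distinct_x:
            raise ValueError(
                f"exposure X must take at least {min_distinct_x} distinct values"
            )
        return self

    def subset(self, index: np.ndarray) -> "IVDataset":
        return IVDataset(
            z=self.z[index],
            x=self.x[index],
            y=self.y[index],
            ids=self.ids[index],
            u=None if self.u is None else self.u[index],
            extra=None if self.extra is None else self.extra.iloc[index].reset_index(drop=True),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"id": self.ids, "Z": self.z, "X": self.x, "Y": self.y})
        if self.extra is not None:
            df = pd.concat([df, self.extra.reset_index(drop=True)], axis=1)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        z_col: str = "Z",
        x_col: str = "X",
        y_col: str = "Y",
        id_col: str = "id",
    ) -> "IVDataset":
        """Build a dataset from a table, dropping rows with missing Z/X/Y."""
        cols = [z_col, x_col, y_col]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        keep = df[cols].notna().all(axis=1)
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.warning("dropped %d rows with missing Z/X/Y", n_dropped)
        df = df.loc[keep].reset_index(drop=True)
        ids = df[id_col].to_numpy() if id_col in df.columns else np.arange(len(df))
        passthrough = [c for c in df.columns if c not in cols + [id_col]]
        extra = df[passthrough].copy() if passthrough else None
        return cls(
            z=df[z_col].to_numpy(float),
            x=df[x_col].to_numpy(float),
            y=df[y_col].to_numpy(float),
            ids=ids,
            extra=extra,
        ).validate()

    @classmethod
    def from_csv(cls, path, **kwargs) -> "IVDataset":
        return cls.from_frame(pd.read_csv(path), **kwargs)
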