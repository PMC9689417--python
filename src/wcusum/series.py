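"""In-memory container for a time-ordered data matrix.

Rows index time (length n), columns index replicates, spatial locations
or pixels (width q; q = 1 for a plain univariate series).  The tests in
this package operate on the row means, so those and the grand mean are
kept alongside the raw values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidInputError


@dataclass(frozen=True)
class SeriesData:
    """An n x q matrix with rows as time points."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim == 1:
            v = v[:, None]
        if v.ndim != 2:
            raise InvalidInputError(f"expected a 1-d or 2-d array, got ndim={v.ndim}")
        if v.shape[0] < 2:
            raise InvalidInputError(f"need at least 2 time points, got {v.shape[0]}")
        if not np.all(np.isfinite(v)):
            raise InvalidInputError("data contain non-finite values")
        object.__setattr__(self, "values", v)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, transpose: bool = False) -> "SeriesData":
        arr = df.to_numpy(dtype=float)
        return cls(arr.T if transpose else arr)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def q(self) -> int:
        return self.values.shape[1]

    @property
    def row_means(self) -> np.ndarray:
        """Per-time-point means across the q replicates."""
        return self.values.mean(axis=1)

    @property
    def grand_mean(self) -> float:
        return float(self.row_means.mean())

    def is_constant(self, rtol: float = 1e-12) -> bool:
        rm = self.row_means
        return bool(np.ptp(rm) <= rtol * max(1.0, float(np.abs(rm).max())))


def as_series_data(data) -> SeriesData:
    """Coerce an array, DataFrame or SeriesData to SeriesData."""
    if isinstance(data, SeriesData):
        return data
    if isinstance(data, pd.DataFrame):
        return SeriesData.from_dataframe(data)
    return SeriesData(np.asarray(data, dtype=float))
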