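"""Core in-memory containers for metabolic-panel time series.

A *panel series* is the raw clinical object: one row per blood draw
(assessment date), one column per retained metabolic index, with a boolean
mask marking cells the laboratory never reported.  A *regular series* is the
derived object the forecaster consumes: the same indices resampled onto a
uniform grid (default 0.5 days) with no missing entries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: The nine metabolic-panel indices retained for dynamical modeling.
INDEX_NAMES: tuple[str, ...] = (
    "Glucose",
    "BUN",
    "Creatinine",
    "Anion Gap",
    "CO2",
    "Chloride",
    "Sodium",
    "Potassium",
    "Calcium",
)


@dataclass
class PanelSeries:
    """Irregularly sampled multivariate panel with a missingness mask.

    Parameters
    ----------
    dates
        Assessment dates, strictly increasing.
    values
        ``(n_visits, n_indices)`` array in native laboratory units.  Cells
        where ``missing_mask`` is True carry NaN.
    index_names
        Column labels, one per index.
    missing_mask
        Boolean array, True where the value was not reported.
    """

    dates: pd.DatetimeIndex
    values: np.ndarray
    index_names: tuple[str, ...] = INDEX_NAMES
    missing_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.values = np.asarray(self.values, dtype=float)
        self.index_names = tuple(self.index_names)
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.values)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (visits x indices) array")
        if self.values.shape[1] != len(self.index_names):
            raise ValueError(
                f"values has {self.values.shape[1]} columns but "
                f"{len(self.index_names)} index names were given"
            )
        if self.missing_mask.shape != self.values.shape:
            raise ValueError("missing_mask shape must match values shape")
        if len(self.dates) != self.values.shape[0]:
            raise ValueError("dates length must match number of rows")
        diffs = np.diff(self.dates.view("int64"))
        if np.any(diffs <= 0):
            raise ValueError("dates must be strictly increasing")
        if not np.all(np.isfinite(self.values[~self.missing_mask])):
            raise ValueError("non-masked values must be finite")

    @property
    def n_visits(self) -> int:
        return self.values.shape[0]

    @property
    def n_indices(self) -> int:
        return self.values.shape[1]

    @property
    def day_offsets(self) -> np.ndarray:
        """Visit times in days since the first visit (float)."""
        delta = self.dates - self.dates[0]
        return delta.total_seconds().to_numpy() / 86400.0

    @property
    def span_days(self) -> float:
        return float(self.day_offsets[-1])

    def copy(self) -> "PanelSeries":
        return PanelSeries(
            dates=self.dates.copy(),
            values=self.values.copy(),
            index_names=self.index_names,
            missing_mask=self.missing_mask.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.dates, columns=list(self.index_names))
        df.index.name = "date"
        return df.mask(self.missing_mask)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PanelSeries):
            return NotImplemented
        return (
            self.index_names == other.index_names
            and self.dates.equals(other.dates)
            and np.array_equal(self.missing_mask, other.missing_mask)
            and np.array_equal(
                self.values[~self.missing_mask], other.values[~other.missing_mask]
            )
        )


@dataclass
class RegularSeries:
    """Uniformly sampled series on a fixed grid (no missing entries)."""

    t0: pd.Timestamp
    step: float
    values: np.ndarray
    index_names: tuple[str, ...] = INDEX_NAMES

    def __post_init__(self) -> None:
        self.t0 = pd.Timestamp(self.t0)
        self.step = float(self.step)
        self.values = np.asarray(self.values, dtype=float)
        self.index_names = tuple(self.index_names)
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.values.ndim != 2 or self.values.shape[1] != len(self.index_names):
            raise ValueError("values must be (n, n_indices)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("regular series may not contain missing values")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_indices(self) -> int:
        return self.values.shape[1]

    @property
    def t_days(self) -> np.ndarray:
        """Grid times in days since ``t0``."""
        return self.step * np.arange(self.n)

    def slice(self, start: int, stop: int) -> "RegularSeries":
        return RegularSeries(
            t0=self.t0 + pd.Timedelta(days=self.step * start),
            step=self.step,
            values=self.values[start:stop].copy(),
            index_names=self.index_names,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.index_names))
        df.insert(0, "t_days", self.t_days)
        return df
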