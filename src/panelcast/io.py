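"""CSV dialects for panel and grid series.

Panel CSV: first column ``date`` (ISO-8601), then one column per index;
an empty cell means the laboratory did not report that value.  Grid CSV:
first column ``t_days`` (0.0, 0.5, ...), then the indices.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import PanelSeries, RegularSeries


class PanelParseError(ValueError):
    """Raised when a panel CSV does not conform to the documented dialect."""


def write_panel_csv(series: PanelSeries, path: str | Path) -> None:
    df = series.to_frame()
    df.index = df.index.strftime("%Y-%m-%d")
    df.index.name = "date"
    df.to_csv(path, na_rep="")


def read_panel_csv(path: str | Path) -> PanelSeries:
    """Read a panel CSV, reporting malformed cells with their location."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.columns[0] != "date":
        raise PanelParseError(f"{path}: first column must be 'date', got {df.columns[0]!r}")
    try:
        dates = pd.to_datetime(df["date"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise PanelParseError(f"{path}: malformed date ({exc})") from exc
    if not dates.is_monotonic_increasing or dates.duplicated().any():
        raise PanelParseError(f"{path}: dates must be strictly increasing")
    index_names = tuple(df.columns[1:])
    n, d = len(df), len(index_names)
    values = np.full((n, d), np.nan)
    mask = np.zeros((n, d), dtype=bool)
    for j, name in enumerate(index_names):
        for i, cell in enumerate(df[name]):
            cell = cell.strip()
            if cell == "":
                mask[i, j] = True
                continue
            try:
                values[i, j] = float(cell)
            except ValueError as exc:
                raise PanelParseError(
                    f"{path}: non-numeric cell {cell!r} at line {i + 2}, column {name!r}"
                ) from exc
    return PanelSeries(
        dates=pd.DatetimeIndex(dates),
        values=values,
        index_names=index_names,
        missing_mask=mask,
    )


def write_regular_csv(series: RegularSeries, path: str | Path) -> None:
    series.to_frame().to_csv(path, index=False)


def read_regular_csv(path: str | Path, t0: str | pd.Timestamp = "1970-01-01") -> RegularSeries:
    df = pd.read_csv(path)
    if df.columns[0] != "t_days":
        raise PanelParseError(f"{path}: first column must be 't_days'")
    t = df["t_days"].to_numpy(dtype=float)
    if len(t) >= 2:
        steps = np.diff(t)
        if not np.allclose(steps, steps[0]):
            raise PanelParseError(f"{path}: t_days grid is not uniform")
        step = float(steps[0])
    else:
        step = 0.5
    return RegularSeries(
        t0=pd.Timestamp(t0),
        step=step,
        values=df.iloc[:, 1:].to_numpy(dtype=float),
        index_names=tuple(df.columns[1:]),
    )
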