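"""Preprocessing of irregular panel series onto the model's uniform grid.

The pipeline order is fixed: neighbor-mean imputation of missing cells,
mu +/- 2*sigma winsorization of outliers (statistics from the visit rows
only), first-order linear interpolation onto a 0.5-day grid, chronological
9:1 train/test split, and per-index zero-mean standardization fitted on the
training rows alone.

For a whole-day span D and a 0.5-day step the grid holds 2*D + 1 rows; a
369-day record therefore yields 739 grid points, of which 665 train and 74
test under the sequential 9:1 split.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import PanelSeries, RegularSeries

logger = logging.getLogger(__name__)


@dataclass
class StandardizationStats:
    """Per-index training mean and unbiased (n-1) standard deviation."""

    mu: np.ndarray
    sigma: np.ndarray
    index_names: tuple[str, ...]
    n_fit: int

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.index_names = tuple(self.index_names)
        if len(self.mu) != len(self.index_names) or len(self.sigma) != len(self.index_names):
            raise ValueError("stats length must equal number of indices")
        if np.any(self.sigma <= 0):
            bad = self.index_names[int(np.argmin(self.sigma))]
            raise ValueError(f"sigma must be strictly positive (index {bad!r})")


@dataclass
class SplitSeries:
    """Chronological train/test views of a regular series."""

    train: RegularSeries
    test: RegularSeries
    ratio: float = 0.9

    @property
    def n(self) -> int:
        return self.train.n + self.test.n

    @property
    def full(self) -> RegularSeries:
        return RegularSeries(
            t0=self.train.t0,
            step=self.train.step,
            values=np.vstack([self.train.values, self.test.values]),
            index_names=self.train.index_names,
        )


def impute_missing(series: PanelSeries) -> PanelSeries:
    """Fill each masked cell with the mean of its two nearest visit neighbors.

    An interior cell takes ``(previous + next) / 2`` along its own index.
    Two consecutive interior missing values in one index are rejected.  A
    missing value at the first or last visit takes its single nearest
    neighbor's value (logged: the neighbor-mean rule has no second neighbor
    there).
    """
    out = series.copy()
    n = out.n_visits
    for j, name in enumerate(out.index_names):
        col_mask = out.missing_mask[:, j]
        if not col_mask.any():
            continue
        idx = np.flatnonzero(col_mask)
        interior = idx[(idx > 0) & (idx < n - 1)]
        consec = interior[np.isin(interior + 1, interior)]
        if consec.size:
            i = int(consec[0])
            raise ValueError(
                f"index {name!r} has consecutive interior missing values at "
                f"{out.dates[i].date()} and {out.dates[i + 1].date()}; "
                "the neighbor-mean rule cannot fill them"
            )
        for i in idx:
            if i == 0:
                out.values[0, j] = out.values[1, j]
                logger.warning(
                    "index %r missing at first visit %s: used nearest neighbor",
                    name, out.dates[0].date(),
                )
            elif i == n - 1:
                out.values[n - 1, j] = out.values[n - 2, j]
                logger.warning(
                    "index %r missing at last visit %s: used nearest neighbor",
                    name, out.dates[n - 1].date(),
                )
            else:
                out.values[i, j] = 0.5 * (out.values[i - 1, j] + out.values[i + 1, j])
    if not np.all(np.isfinite(out.values)):
        raise ValueError("imputation left non-finite values (boundary cascade?)")
    out.missing_mask = np.zeros_like(out.missing_mask)
    return out


def winsorize(
    series: PanelSeries,
    k: float = 2.0,
    stats: tuple[np.ndarray, np.ndarray] | None = None,
) -> PanelSeries:
    """Clip per-index values to ``mu +/- k*sigma`` in a single pass.

    By default ``mu`` and the sample (n-1) standard deviation are computed
    once from the pre-clipping visit rows; there is no iteration.  Note that
    recomputing the statistics on the clipped output yields narrower bounds
    (clipping shrinks both moments), so a *recomputed* second pass would clip
    further: single-pass moment-based winsorization is idempotent only in
    the sense of re-applying the same thresholds, which callers get by
    passing the first pass's ``stats`` (a ``(mu, sigma)`` pair) explicitly.

    Requires an already-imputed series (no missing cells).
    """
    if series.missing_mask.any():
        raise ValueError("winsorize requires a fully imputed series (no missing cells)")
    out = series.copy()
    if stats is None:
        mu = out.values.mean(axis=0)
        sigma = out.values.std(axis=0, ddof=1)
    else:
        mu, sigma = (np.asarray(a, dtype=float) for a in stats)
    for j, name in enumerate(out.index_names):
        if sigma[j] == 0:
            logger.warning("index %r is constant; winsorization skipped", name)
            continue
        lo, hi = mu[j] - k * sigma[j], mu[j] + k * sigma[j]
        out.values[:, j] = np.clip(out.values[:, j], lo, hi)
    return out


def winsor_stats(series: PanelSeries) -> tuple[np.ndarray, np.ndarray]:
    """The ``(mu, sigma)`` pair :func:`winsorize` uses by default."""
    if series.missing_mask.any():
        raise ValueError("winsor_stats requires a fully imputed series")
    return series.values.mean(axis=0), series.values.std(axis=0, ddof=1)


def interpolate_uniform(series: PanelSeries, step: float = 0.5) -> RegularSeries:
    """Resample onto a uniform grid by first-order (piecewise-linear)
    interpolation between visits.

    The grid starts at the first visit date and, when the span is a whole
    multiple of the step, ends exactly at the last visit date; grid points
    that coincide with visit dates reproduce the visit values exactly.
    """
    if series.n_visits < 2:
        raise ValueError("interpolation requires at least 2 visits")
    if series.missing_mask.any():
        raise ValueError("interpolate_uniform requires a fully imputed series")
    t = series.day_offsets
    n_grid = int(math.floor(series.span_days / step + 1e-9)) + 1
    grid = step * np.arange(n_grid)
    values = np.column_stack(
        [np.interp(grid, t, series.values[:, j]) for j in range(series.n_indices)]
    )
    return RegularSeries(
        t0=series.dates[0], step=step, values=values, index_names=series.index_names
    )


def sequential_split(series: RegularSeries, ratio: float = 0.9) -> SplitSeries:
    """Chronological split: first ``floor(ratio * n)`` rows train, rest test."""
    n = series.n
    if n < 10:
        raise ValueError("series too short to split (need n >= 10)")
    n_train = int(math.floor(ratio * n))
    return SplitSeries(
        train=series.slice(0, n_train),
        test=series.slice(n_train, n),
        ratio=ratio,
    )


def fit_standardizer(train: RegularSeries) -> StandardizationStats:
    """Per-index mean and unbiased standard deviation of the training rows."""
    if train.n < 2:
        raise ValueError("need at least 2 training rows to fit a standardizer")
    mu = train.values.mean(axis=0)
    sigma = train.values.std(axis=0, ddof=1)
    if np.any(sigma == 0):
        bad = train.index_names[int(np.argmin(sigma))]
        raise ValueError(f"index {bad!r} is constant on the training rows")
    return StandardizationStats(mu=mu, sigma=sigma, index_names=train.index_names, n_fit=train.n)


def apply_standardizer(series: RegularSeries, stats: StandardizationStats) -> RegularSeries:
    """Map each value to ``(x - mu_j) / sigma_j``; inverse of
    :func:`panelcast.evaluation.destandardize`."""
    if series.index_names != stats.index_names:
        raise ValueError("index names of series and standardizer do not match")
    return RegularSeries(
        t0=series.t0,
        step=series.step,
        values=(series.values - stats.mu) / stats.sigma,
        index_names=series.index_names,
    )


def correlation_screen(series: RegularSeries, threshold: float = 0.80) -> pd.DataFrame:
    """Pairwise correlation matrix of the grid values, with a flag per pair.

    Returns a tidy frame of the strictly-upper-triangle pairs with columns
    ``index_a``, ``index_b``, ``r``, ``flagged`` (|r| >= threshold).  Highly
    collinear pairs would make one index redundant as a state variable.
    """
    R = np.corrcoef(series.values, rowvar=False)
    rows = []
    d = series.n_indices
    for a in range(d):
        for b in range(a + 1, d):
            rows.append(
                {
                    "index_a": series.index_names[a],
                    "index_b": series.index_names[b],
                    "r": R[a, b],
                    "flagged": bool(abs(R[a, b]) >= threshold),
                }
            )
    return pd.DataFrame(rows)


def preprocess_panel(
    series: PanelSeries,
    step: float = 0.5,
    ratio: float = 0.9,
    winsor_k: float = 2.0,
) -> tuple[SplitSeries, StandardizationStats, RegularSeries]:
    """Full pipeline: impute -> winsorize -> interpolate -> split -> fit stats.

    Returns the chronological split (still on the dimensional scale), the
    training-rows standardizer, and the interpolated grid series.
    """
    clean = winsorize(impute_missing(series), k=winsor_k)
    grid = interpolate_uniform(clean, step=step)
    split = sequential_split(grid, ratio=ratio)
    stats = fit_standardizer(split.train)
    return split, stats, grid
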