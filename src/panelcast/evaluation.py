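"""Per-index forecast metrics on the dimensional (laboratory-unit) scale.

Predictions leave the network as standardized, dimensionless quantities and
are mapped back to native units, ``y_hat = y_bar * sigma_j + mu_j``, before
any metric is computed.  The suite per index:

* RMSE — root mean squared error, in the index's own units;
* NSE — Nash–Sutcliffe efficiency, ``1 - SSE/SST`` against the observed
  mean (1 perfect, 0 no better than the mean predictor);
* relative L1 error — mean of ``|y - y_hat| / |y|`` (the MAPE);
* relative L-infinity error — max of ``|y - y_hat| / |y|``.

Relative errors are undefined where an observation is zero (a small
denominator makes them explode even for good fits — the known failure mode
of MAPE-style metrics on near-zero analytes); such indices are flagged and
their RMSE/NSE still reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import StandardizationStats
from .model import ForecastModel
from .windowing import WindowDataset


@dataclass
class EvalReport:
    """Per-index and aggregate metrics for one model/test-set combination."""

    per_index: pd.DataFrame  # rows: indices; columns rmse, nse, rel_l1, rel_linf
    aggregate: dict[str, float]
    n_eval: int
    undefined_relative: tuple[str, ...] = ()

    def to_csv(self, path: str | Path) -> None:
        self.per_index.to_csv(path, index_label="index")

    def to_text(self) -> str:
        lines = [self.per_index.to_string(float_format=lambda v: f"{v:.6g}")]
        lines.append("")
        for k, v in self.aggregate.items():
            lines.append(f"{k}: {v:.6g}")
        if self.undefined_relative:
            lines.append(
                "relative errors undefined (zero observations): "
                + ", ".join(self.undefined_relative)
            )
        return "\n".join(lines)


def destandardize(pred: np.ndarray, stats: StandardizationStats) -> np.ndarray:
    """Invert the zero-mean standardization: ``y_hat = y_bar * sigma + mu``."""
    pred = np.asarray(pred, dtype=float)
    d = len(stats.mu)
    if pred.shape[-1] != d:
        raise ValueError(
            f"prediction width {pred.shape[-1]} != {d} standardized indices"
        )
    return pred * stats.sigma + stats.mu


def compute_metrics(
    pred: np.ndarray,
    obs: np.ndarray,
    index_names: tuple[str, ...] | None = None,
) -> EvalReport:
    """Metric suite over aligned dimensional prediction/observation series.

    Both arguments are ``(n, d)`` (a single column may be passed as
    ``(n, 1)``).  Requires ``n >= 2`` so SST is meaningful.
    """
    pred = np.atleast_2d(np.asarray(pred, float))
    obs = np.atleast_2d(np.asarray(obs, float))
    if pred.shape != obs.shape:
        raise ValueError("prediction and observation shapes differ")
    n, d = obs.shape
    if n < 2:
        raise ValueError("need at least 2 evaluation points")
    if index_names is None:
        index_names = tuple(f"Index{j+1}" for j in range(d))
    rows = []
    undefined = []
    for j, name in enumerate(index_names):
        y, yh = obs[:, j], pred[:, j]
        err = y - yh
        rmse = float(np.sqrt(np.mean(err**2)))
        sst = float(np.sum((y - y.mean()) ** 2))
        nse = 1.0 - float(np.sum(err**2)) / sst if sst > 0 else np.nan
        if np.any(y == 0):
            undefined.append(name)
            rel_l1 = rel_linf = np.nan
        else:
            rel = np.abs(err) / np.abs(y)
            rel_l1 = float(np.mean(rel))
            rel_linf = float(np.max(rel))
        rows.append({"rmse": rmse, "nse": nse, "rel_l1": rel_l1, "rel_linf": rel_linf})
    per_index = pd.DataFrame(rows, index=list(index_names))
    aggregate = {
        "mean_rel_l1": float(np.nanmean(per_index["rel_l1"])) if d else np.nan,
        "max_rel_l1": float(np.nanmax(per_index["rel_l1"])),
        "max_rel_linf": float(np.nanmax(per_index["rel_linf"])),
    }
    return EvalReport(
        per_index=per_index,
        aggregate=aggregate,
        n_eval=n,
        undefined_relative=tuple(undefined),
    )


def evaluate_model(
    model: ForecastModel,
    test_pairs: WindowDataset,
    stats: StandardizationStats,
    per_horizon: bool = False,
) -> EvalReport | dict[int, EvalReport]:
    """Forward every test window, destandardize, and score.

    Multi-step predictions pool all ``L`` horizons into one set of points
    per index (one number per design, as in the summary tables); pass
    ``per_horizon=True`` for a horizon-by-horizon breakdown.  The
    sequence-output design pools its ``T`` per-step predictions likewise.
    """
    if len(test_pairs) == 0:
        raise ValueError("empty test set")
    d = len(stats.mu)
    pred = model.forward(test_pairs.inputs)
    obs = test_pairs.targets
    if test_pairs.sequence_targets:  # (N, T, d)
        pred3 = pred
        obs3 = obs
    elif pred.shape[1] > d:  # multi-step flattened (N, d*L)
        L = pred.shape[1] // d
        pred3 = pred.reshape(len(pred), L, d)
        obs3 = obs.reshape(len(obs), L, d)
    else:
        pred3 = pred[:, None, :]
        obs3 = obs[:, None, :]
    if per_horizon:
        return {
            h + 1: compute_metrics(
                destandardize(pred3[:, h], stats),
                destandardize(obs3[:, h], stats),
                stats.index_names,
            )
            for h in range(pred3.shape[1])
        }
    pred_flat = destandardize(pred3.reshape(-1, d), stats)
    obs_flat = destandardize(obs3.reshape(-1, d), stats)
    return compute_metrics(pred_flat, obs_flat, stats.index_names)


def write_report(report: EvalReport, path: str | Path) -> None:
    """CSV (one row per index) next to a human-readable text table."""
    path = Path(path)
    report.to_csv(path)
    path.with_suffix(".txt").write_text(report.to_text() + "\n")
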