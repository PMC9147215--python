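"""End-to-end orchestration: raw panel CSV (or synthetic draw) through
preprocessing, windowing, training, evaluation, and reporting.

Every run writes a self-contained run directory: the interpolated grid CSV,
split summary, standardization stats, model checkpoint, per-epoch loss log,
evaluation report, and a machine-readable manifest holding every config and
the seed, from which the run can be reproduced bit for bit.

All randomness flows from one top-level seed, fanned out deterministically
to the generator, the weight initialization, and the batch shuffling.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .containers import PanelSeries
from .io import read_panel_csv, write_panel_csv, write_regular_csv
from .model import ModelConfig, init_model
from .preprocess import preprocess_panel
from .synthetic import SyntheticConfig, generate_panel
from .training import (
    DEFAULT_EPSILON,
    TrainConfig,
    fit_design,
    standardized_pairs,
    sweep_time_step,
    transfer,
)
from .evaluation import evaluate_model, write_report
from .windowing import WindowSpec

logger = logging.getLogger(__name__)

_MODES = ("onestep", "stacked", "multistep", "sweep", "transfer")


def _fan_out(seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds derived from the top-level seed."""
    ss = np.random.SeedSequence(seed)
    gen, init, shuffle, patient2 = ss.spawn(4)
    mod = 2**31
    return {
        "generator": int(gen.generate_state(1)[0] % mod),
        "init": int(init.generate_state(1)[0] % mod),
        "shuffle": int(shuffle.generate_state(1)[0] % mod),
        "second_patient": int(patient2.generate_state(1)[0] % mod),
    }


@dataclass
class PipelineConfig:
    """One fully specified run: input source, window geometry, training."""

    mode: str = "onestep"
    input_path: str | None = None
    synthetic: SyntheticConfig | None = None
    window: WindowSpec = field(default_factory=lambda: WindowSpec(T=2))
    model: ModelConfig | None = None
    train: TrainConfig | None = None
    T_range: tuple[int, ...] = tuple(range(1, 11))
    sweep_metric: str = "rel_linf"
    output_dir: str = "runs/latest"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")
        if (self.input_path is None) == (self.synthetic is None):
            raise ValueError("exactly one input source (input_path or synthetic) required")
        if self.mode == "stacked" and self.window.S < 1:
            raise ValueError("stacked mode requires S >= 1")
        if self.train is None:
            eps = DEFAULT_EPSILON.get(self.mode, DEFAULT_EPSILON["onestep"])
            self.train = TrainConfig(epsilon=eps, seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "synthetic" in raw and raw["synthetic"] is not None:
            syn = dict(raw["synthetic"])
            for key in ("target_corr", "index_means", "index_sds"):
                if key in syn:
                    syn[key] = np.asarray(syn[key], dtype=float)
            raw["synthetic"] = SyntheticConfig(**syn)
        if "window" in raw:
            raw["window"] = WindowSpec(**raw["window"])
        if "model" in raw and raw["model"] is not None:
            raw["model"] = ModelConfig(**raw["model"])
        if "train" in raw and raw["train"] is not None:
            raw["train"] = TrainConfig(**raw["train"])
        if "T_range" in raw:
            raw["T_range"] = tuple(raw["T_range"])
        return cls(**raw)

    def manifest(self) -> dict:
        def clean(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            return obj

        return {
            "package_version": __version__,
            "mode": self.mode,
            "seed": self.seed,
            "input_path": self.input_path,
            "synthetic": clean(asdict(self.synthetic)) if self.synthetic else None,
            "window": asdict(self.window),
            "model": asdict(self.model) if self.model else None,
            "train": asdict(self.train),
            "T_range": list(self.T_range),
            "sweep_metric": self.sweep_metric,
        }


def _load_panel(cfg: PipelineConfig, seeds: dict[str, int]) -> PanelSeries:
    if cfg.input_path is not None:
        return read_panel_csv(cfg.input_path)
    syn = cfg.synthetic
    syn = SyntheticConfig(**{**asdict(syn), "seed": seeds["generator"]})
    return generate_panel(syn)


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute one configured run; returns the run directory."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _fan_out(cfg.seed)
    stage = "load"
    try:
        panel = _load_panel(cfg, seeds)
        write_panel_csv(panel, out / "panel.csv")

        stage = "preprocess"
        split, stats, grid = preprocess_panel(panel)
        write_regular_csv(grid, out / "interpolated.csv")
        (out / "split.json").write_text(json.dumps({
            "n": grid.n, "train": split.train.n, "test": split.test.n,
            "ratio": split.ratio,
        }, indent=2))
        (out / "standardization.json").write_text(json.dumps({
            "mu": stats.mu.tolist(), "sigma": stats.sigma.tolist(),
            "index_names": list(stats.index_names), "n_fit": stats.n_fit,
        }, indent=2))

        tc = TrainConfig(**{**asdict(cfg.train), "seed": seeds["shuffle"]})
        if cfg.mode == "sweep":
            stage = "sweep"
            table, selected = sweep_time_step(
                split, list(cfg.T_range), tc, metric=cfg.sweep_metric, stats=stats
            )
            table.to_csv(out / "sweep.csv", index=False)
            (out / "sweep_selected.json").write_text(
                json.dumps({"selected_T": selected, "metric": cfg.sweep_metric})
            )
        elif cfg.mode == "transfer":
            stage = "transfer"
            master_split, master_stats, _ = split, stats, grid
            mc = cfg.model or ModelConfig(
                d_in=split.train.n_indices * cfg.window.S,
                d_out=split.train.n_indices * cfg.window.L
                if cfg.window.S == 1 else split.train.n_indices,
                sequence_output=cfg.window.S > 1,
                seed=seeds["init"],
            )
            master = fit_design(master_split, master_stats, cfg.window, tc, mc)
            syn2 = SyntheticConfig(
                **{**asdict(cfg.synthetic or SyntheticConfig()),
                   "seed": seeds["second_patient"]}
            )
            panel2 = generate_panel(syn2)
            split2, stats2, _ = preprocess_panel(panel2)
            result = transfer(master.model, split2, tc, spec=cfg.window)
            result.history.to_csv(out / "loss_log.csv", index=False)
            result.model.save(out / "model.npz")
            _, test_pairs = standardized_pairs(split2, stats2, cfg.window)
            report = evaluate_model(result.model, test_pairs, stats2)
            write_report(report, out / "eval_report.csv")
        else:
            stage = "train"
            mc = cfg.model
            if mc is None:
                d = split.train.n_indices
                mc = ModelConfig(
                    d_in=d * cfg.window.S,
                    d_out=d if cfg.window.S > 1 else d * cfg.window.L,
                    sequence_output=cfg.window.S > 1,
                    seed=seeds["init"],
                )
            result = fit_design(split, stats, cfg.window, tc, mc)
            result.history.to_csv(out / "loss_log.csv", index=False)
            result.model.save(out / "model.npz")
            stage = "evaluate"
            _, test_pairs = standardized_pairs(split, stats, cfg.window)
            report = evaluate_model(result.model, test_pairs, stats)
            write_report(report, out / "eval_report.csv")
    except Exception:
        logger.exception("pipeline failed at stage %r", stage)
        raise
    (out / "manifest.json").write_text(json.dumps(cfg.manifest(), indent=2))
    return out
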