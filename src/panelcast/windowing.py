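"""Sliding-window supervised pair construction from a standardized grid series.

Three designs are supported, all consuming a series ``x_1 .. x_n`` of
standardized 9-vectors:

* **one-step** — input the ``T`` consecutive vectors ``x_i .. x_{i+T-1}``,
  target the next vector ``x_{i+T}``; ``n - T`` pairs.
* **input-stacked** — each raw vector is replaced by the concatenation
  ``X_i = [x_i, ..., x_{i+S-1}]`` of ``S`` consecutive vectors; the input is
  the sequence ``X_i .. X_{i+T-1}`` and the target is the per-step sequence
  ``x_{i+S} .. x_{i+T+S-1}``; ``n - T - S + 1`` pairs.
* **multi-step** — input as in one-step, target the next ``L`` vectors
  flattened to a ``9L``-vector; ``n - T - L + 1`` pairs.

Windows are presented to the recurrent core as ``T`` time steps of
``d_in``-vectors (a sequence), never as one flattened vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import RegularSeries


@dataclass(frozen=True)
class WindowSpec:
    """Window geometry: time steps ``T``, stack number ``S``, horizon ``L``."""

    T: int
    S: int = 1
    L: int = 1

    def __post_init__(self) -> None:
        if not (1 <= self.T <= 10):
            raise ValueError("T must lie in 1..10")
        if self.S < 1 or self.L < 1:
            raise ValueError("S and L must be >= 1")
        if self.S > 1 and self.L > 1:
            raise ValueError("stacking (S>1) and multi-step (L>1) are not combined")


@dataclass
class WindowDataset:
    """Ordered supervised pairs.

    ``inputs`` has shape ``(N, T, d_in)``.  ``targets`` has shape
    ``(N, d_out)`` for the one-step and multi-step designs and
    ``(N, T, d_out)`` for the input-stacked (sequence-output) design.
    ``origin_offsets[i]`` is the source row index (0-based) of the first raw
    vector entering pair ``i``.
    """

    inputs: np.ndarray
    targets: np.ndarray
    spec: WindowSpec
    origin_offsets: np.ndarray

    def __post_init__(self) -> None:
        if len(self.inputs) != len(self.targets):
            raise ValueError("inputs and targets must pair up")
        if len(self.inputs) != len(self.origin_offsets):
            raise ValueError("origin_offsets must pair with inputs")

    def __len__(self) -> int:
        return len(self.inputs)

    @property
    def sequence_targets(self) -> bool:
        return self.targets.ndim == 3

    def subset(self, idx: np.ndarray) -> "WindowDataset":
        return WindowDataset(
            inputs=self.inputs[idx],
            targets=self.targets[idx],
            spec=self.spec,
            origin_offsets=self.origin_offsets[idx],
        )

    def dump_csv(self, path: str | Path) -> None:
        """Debug dump: one row per pair, flattened input then target."""
        flat_in = self.inputs.reshape(len(self), -1)
        flat_tg = self.targets.reshape(len(self), -1)
        df = pd.DataFrame(
            np.hstack([self.origin_offsets[:, None], flat_in, flat_tg]),
            columns=["origin"]
            + [f"z{k}" for k in range(flat_in.shape[1])]
            + [f"y{k}" for k in range(flat_tg.shape[1])],
        )
        df.to_csv(path, index=False)


def _values(series: RegularSeries | np.ndarray) -> np.ndarray:
    return series.values if isinstance(series, RegularSeries) else np.asarray(series, float)


def make_onestep(series: RegularSeries | np.ndarray, T: int) -> WindowDataset:
    """One-step pairs: input ``x_i..x_{i+T-1}``, target ``x_{i+T}``."""
    x = _values(series)
    n = len(x)
    if n <= T:
        raise ValueError(f"series of length {n} cannot form windows with T={T}")
    N = n - T
    inputs = np.stack([x[i : i + T] for i in range(N)])
    targets = x[T:].copy()
    return WindowDataset(
        inputs=inputs,
        targets=targets,
        spec=WindowSpec(T=T),
        origin_offsets=np.arange(N),
    )


def make_stacked(series: RegularSeries | np.ndarray, T: int, S: int) -> WindowDataset:
    """Input-stacked sequence-to-sequence pairs.

    Stacked vector ``X_i`` concatenates ``x_i..x_{i+S-1}``; pair ``i`` has
    input sequence ``X_i..X_{i+T-1}`` and per-step targets
    ``x_{i+S}..x_{i+T+S-1}``.
    """
    x = _values(series)
    n, d = x.shape
    if n < T + S:
        raise ValueError(f"series of length {n} too short for T={T}, S={S}")
    # stacked vectors X_i, i = 0..n-S
    m = n - S + 1
    stacked = np.hstack([x[k : k + m] for k in range(S)])  # (m, d*S)
    N = n - T - S + 1
    inputs = np.stack([stacked[i : i + T] for i in range(N)])
    targets = np.stack([x[i + S : i + S + T] for i in range(N)])  # (N, T, d)
    return WindowDataset(
        inputs=inputs,
        targets=targets,
        spec=WindowSpec(T=T, S=S),
        origin_offsets=np.arange(N),
    )


def make_multistep(series: RegularSeries | np.ndarray, T: int, L: int) -> WindowDataset:
    """Multi-step pairs: input ``x_i..x_{i+T-1}``, target the next ``L``
    vectors flattened to one ``d*L`` vector."""
    x = _values(series)
    n, d = x.shape
    if n < T + L:
        raise ValueError(f"series of length {n} too short for T={T}, L={L}")
    N = n - T - L + 1
    inputs = np.stack([x[i : i + T] for i in range(N)])
    targets = np.stack([x[i + T : i + T + L].reshape(-1) for i in range(N)])
    return WindowDataset(
        inputs=inputs,
        targets=targets,
        spec=WindowSpec(T=T, L=L),
        origin_offsets=np.arange(N),
    )


def make_windows(series: RegularSeries | np.ndarray, spec: WindowSpec) -> WindowDataset:
    if spec.S > 1:
        return make_stacked(series, spec.T, spec.S)
    if spec.L > 1:
        return make_multistep(series, spec.T, spec.L)
    return make_onestep(series, spec.T)


def split_pairs(dataset: WindowDataset, n_train: int) -> tuple[WindowDataset, WindowDataset]:
    """Partition pairs built from the *full* series by where their targets fall.

    Training pairs are those whose targets lie entirely within the first
    ``n_train`` source rows; test pairs are those whose targets lie entirely
    in the remaining rows (their inputs may reach back into training rows).
    For the one-step design on an ``n``-row grid this yields ``n_train - T``
    training pairs and ``n - n_train`` test pairs for every ``T`` —
    665 - T and 74 on the reference 739/665 split.  With ``L > 1`` or
    ``S > 1`` the few pairs whose targets straddle the boundary belong to
    neither side (leakage guard).
    """
    spec = dataset.spec
    offs = dataset.origin_offsets
    first_target = offs + (spec.S if spec.S > 1 else spec.T)
    n_targets = spec.T if spec.S > 1 else spec.L
    last_target = first_target + n_targets - 1
    train_idx = np.flatnonzero(last_target <= n_train - 1)
    test_idx = np.flatnonzero(first_target >= n_train)
    return dataset.subset(train_idx), dataset.subset(test_idx)
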