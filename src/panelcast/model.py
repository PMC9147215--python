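"""Stacked-LSTM forecaster: a pair of LSTM cells in series feeding a fully
connected output head.

Each cell follows the standard gated recurrence

    f_t = sigmoid(W_f [h_{t-1}, x_t] + b_f)        (forget gate)
    i_t = sigmoid(W_i [h_{t-1}, x_t] + b_i)        (input gate)
    g_t = tanh   (W_c [h_{t-1}, x_t] + b_c)        (candidate state)
    c_t = f_t * c_{t-1} + i_t * g_t                (cell state)
    o_t = sigmoid(W_o [h_{t-1}, x_t] + b_o)        (output gate)
    h_t = o_t * tanh(c_t)

with zero initial hidden and cell states.  Cell k consumes cell k-1's hidden
sequence.  For the one-step and multi-step designs the head maps the final
top-cell hidden state to the output; for the input-stacked sequence-output
design it maps every top-cell hidden state.

The output head is affine (linear) by default: targets are zero-mean
standardized values that lie outside (0, 1), which a sigmoid output could
not reach.  A sigmoid head remains available as a config option for
squashed-output experiments.

Everything is plain NumPy.  :func:`cell_step` is the deliberately scalar,
loop-based reference recurrence; the vectorized training path in
:mod:`panelcast.training` is validated against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .preprocess import StandardizationStats

_SCHEMA_VERSION = 1


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class ModelConfig:
    """Architecture of the forecaster.

    ``d_in`` is 9 for the plain designs and ``9*S`` for the input-stacked
    design; ``d_out`` is 9, ``9*L`` for multi-step, or per-step 9 for the
    sequence-output design (with ``sequence_output=True``).  ``hidden`` is
    the recurrent state width of every cell; ``n_cells`` stacked cells
    default to the pair-in-series layout, and ``head_layers`` lists hidden
    widths of the fully connected head (empty = single affine layer).
    """

    d_in: int = 9
    d_out: int = 9
    hidden: int = 64
    n_cells: int = 2
    head_layers: tuple[int, ...] = ()
    output_activation: str = "linear"
    sequence_output: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.head_layers = tuple(self.head_layers)
        if self.d_in < 1 or self.d_out < 1 or self.hidden < 1 or self.n_cells < 1:
            raise ValueError("d_in, d_out, hidden, n_cells must all be >= 1")
        if self.output_activation not in ("linear", "sigmoid"):
            raise ValueError("output_activation must be 'linear' or 'sigmoid'")


class ForecastModel:
    """A configured parameter set plus the standardization stats needed to
    map predictions back to laboratory units.

    Parameters are held in a flat ``dict[str, np.ndarray]``:
    ``lstm{k}_Wx`` (d, 4H), ``lstm{k}_Wh`` (H, 4H), ``lstm{k}_b`` (4H,) per
    cell (gate order f, i, g, o along the last axis), and ``head{m}_W`` /
    ``head{m}_b`` for the fully connected head.
    """

    def __init__(
        self,
        config: ModelConfig,
        params: dict[str, np.ndarray],
        stats: StandardizationStats | None = None,
    ) -> None:
        self.config = config
        self.params = params
        self.stats = stats

    # -- architecture helpers -------------------------------------------------

    @staticmethod
    def param_shapes(config: ModelConfig) -> dict[str, tuple[int, ...]]:
        H = config.hidden
        shapes: dict[str, tuple[int, ...]] = {}
        d = config.d_in
        for k in range(config.n_cells):
            shapes[f"lstm{k}_Wx"] = (d, 4 * H)
            shapes[f"lstm{k}_Wh"] = (H, 4 * H)
            shapes[f"lstm{k}_b"] = (4 * H,)
            d = H
        widths = (H, *config.head_layers, config.d_out)
        for m in range(len(widths) - 1):
            shapes[f"head{m}_W"] = (widths[m], widths[m + 1])
            shapes[f"head{m}_b"] = (widths[m + 1],)
        return shapes

    @property
    def n_head_layers(self) -> int:
        return len(self.config.head_layers) + 1

    def copy(self) -> "ForecastModel":
        return ForecastModel(
            config=ModelConfig(**asdict(self.config)),
            params={k: v.copy() for k, v in self.params.items()},
            stats=self.stats,
        )

    # -- forward --------------------------------------------------------------

    def forward(self, windows: np.ndarray, return_states: bool = False):
        """Run a batch of windows through the stacked recurrence and head.

        ``windows`` is ``(B, T, d_in)`` or a single ``(T, d_in)`` window.
        Returns ``(B, d_out)`` predictions, or ``(B, T, d_out)`` when the
        config requests sequence output.
        """
        x = np.asarray(windows, dtype=float)
        single = x.ndim == 2
        if single:
            x = x[None]
        if x.shape[2] != self.config.d_in:
            raise ValueError(
                f"window width {x.shape[2]} != configured d_in {self.config.d_in}"
            )
        B, T, _ = x.shape
        H = self.config.hidden
        seq = x
        hs = None
        for k in range(self.config.n_cells):
            Wx = self.params[f"lstm{k}_Wx"]
            Wh = self.params[f"lstm{k}_Wh"]
            b = self.params[f"lstm{k}_b"]
            h = np.zeros((B, H))
            c = np.zeros((B, H))
            hs = np.empty((B, T, H))
            for t in range(T):
                z = seq[:, t] @ Wx + h @ Wh + b
                f = sigmoid(z[:, :H])
                i = sigmoid(z[:, H : 2 * H])
                g = np.tanh(z[:, 2 * H : 3 * H])
                o = sigmoid(z[:, 3 * H :])
                c = f * c + i * g
                h = o * np.tanh(c)
                hs[:, t] = h
            seq = hs
        if self.config.sequence_output:
            out = self._head(hs.reshape(B * T, H)).reshape(B, T, -1)
        else:
            out = self._head(hs[:, -1])
        if single:
            out = out[0]
        return out

    def _head(self, h: np.ndarray) -> np.ndarray:
        a = h
        for m in range(self.n_head_layers):
            a = a @ self.params[f"head{m}_W"] + self.params[f"head{m}_b"]
            if m < self.n_head_layers - 1:
                a = np.tanh(a)
        if self.config.output_activation == "sigmoid":
            a = sigmoid(a)
        return a

    # -- persistence ----------------------------------------------------------

    def save(self, path) -> None:
        """Single self-describing archive: config, parameters, stats."""
        meta = {"schema_version": _SCHEMA_VERSION, "config": asdict(self.config)}
        if self.stats is not None:
            meta["stats"] = {
                "mu": self.stats.mu.tolist(),
                "sigma": self.stats.sigma.tolist(),
                "index_names": list(self.stats.index_names),
                "n_fit": self.stats.n_fit,
            }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **self.params)

    @classmethod
    def load(cls, path) -> "ForecastModel":
        with np.load(path) as archive:
            meta = json.loads(bytes(archive["__meta__"]).decode())
            if meta["schema_version"] != _SCHEMA_VERSION:
                raise ValueError(f"unsupported checkpoint schema {meta['schema_version']}")
            cfg = meta["config"]
            cfg["head_layers"] = tuple(cfg["head_layers"])
            config = ModelConfig(**cfg)
            params = {k: archive[k].copy() for k in archive.files if k != "__meta__"}
        stats = None
        if "stats" in meta:
            s = meta["stats"]
            stats = StandardizationStats(
                mu=np.array(s["mu"]),
                sigma=np.array(s["sigma"]),
                index_names=tuple(s["index_names"]),
                n_fit=s["n_fit"],
            )
        return cls(config=config, params=params, stats=stats)


def init_model(config: ModelConfig, stats: StandardizationStats | None = None) -> ForecastModel:
    """Small-scale uniform initialization, U(-1/sqrt(H), 1/sqrt(H)),
    reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    bound = 1.0 / np.sqrt(config.hidden)
    params = {
        name: rng.uniform(-bound, bound, size=shape)
        for name, shape in ForecastModel.param_shapes(config).items()
    }
    return ForecastModel(config=config, params=params, stats=stats)


# -- scalar reference implementation (oracle) ---------------------------------


def cell_step(
    x_t: np.ndarray,
    h_prev: np.ndarray,
    c_prev: np.ndarray,
    params: dict[str, np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM recurrence, evaluated gate by gate with explicit scalar loops.

    ``params`` holds ``Wf, Wi, Wc, Wo`` of shape ``(H, H + d)`` acting on the
    concatenation ``[h_prev, x_t]``, and biases ``bf, bi, bc, bo`` of shape
    ``(H,)``.  Kept intentionally un-vectorized as an independent reference
    for the batched forward pass.
    """
    H = len(h_prev)
    hx = np.concatenate([h_prev, x_t])
    h_t = np.empty(H)
    c_t = np.empty(H)
    for r in range(H):
        zf = sum(params["Wf"][r, q] * hx[q] for q in range(len(hx))) + params["bf"][r]
        zi = sum(params["Wi"][r, q] * hx[q] for q in range(len(hx))) + params["bi"][r]
        zc = sum(params["Wc"][r, q] * hx[q] for q in range(len(hx))) + params["bc"][r]
        zo = sum(params["Wo"][r, q] * hx[q] for q in range(len(hx))) + params["bo"][r]
        f = 1.0 / (1.0 + np.exp(-zf))
        i = 1.0 / (1.0 + np.exp(-zi))
        g = np.tanh(zc)
        o = 1.0 / (1.0 + np.exp(-zo))
        c_t[r] = f * c_prev[r] + i * g
        h_t[r] = o * np.tanh(c_t[r])
    return h_t, c_t


def split_gate_params(model: ForecastModel, cell: int) -> dict[str, np.ndarray]:
    """Re-express one cell's packed parameters in per-gate ``(H, H+d)`` form
    for :func:`cell_step`."""
    H = model.config.hidden
    Wx = model.params[f"lstm{cell}_Wx"]  # (d, 4H)
    Wh = model.params[f"lstm{cell}_Wh"]  # (H, 4H)
    b = model.params[f"lstm{cell}_b"]
    out: dict[str, np.ndarray] = {}
    for idx, gate in enumerate(("f", "i", "c", "o")):
        sl = slice(idx * H, (idx + 1) * H)
        out[f"W{gate}"] = np.hstack([Wh[:, sl].T, Wx[:, sl].T])  # (H, H+d)
        out[f"b{gate}"] = b[sl].copy()
    return out


def reference_forward(model: ForecastModel, window: np.ndarray) -> np.ndarray:
    """Forward pass of a single window built purely from :func:`cell_step`
    chains — the sequence-level oracle for :meth:`ForecastModel.forward`."""
    window = np.asarray(window, dtype=float)
    T = window.shape[0]
    H = model.config.hidden
    seq = [window[t] for t in range(T)]
    for k in range(model.config.n_cells):
        gp = split_gate_params(model, k)
        h = np.zeros(H)
        c = np.zeros(H)
        outs = []
        for t in range(T):
            h, c = cell_step(seq[t], h, c, gp)
            outs.append(h)
        seq = outs
    if model.config.sequence_output:
        return np.stack([model._head(h[None])[0] for h in seq])
    return model._head(seq[-1][None])[0]
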