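"""Three-layer LSTM sequence regressor with CMC/RMSE evaluation.

The cell follows the standard gated recurrence

    f_t = sigma(W_f [h_{t-1}, x_t] + b_f)          (forget gate)
    i_t = sigma(W_i [h_{t-1}, x_t] + b_i)          (input gate)
    C~_t = tanh(W_C [h_{t-1}, x_t] + b_C)          (candidate cell state)
    C_t = f_t * C_{t-1} + i_t * C~_t
    o_t = sigma(W_o [h_{t-1}, x_t] + b_o)          (output gate)
    h_t = o_t * tanh(C_t)

Three cells are stacked (layer l consumes layer l-1's hidden sequence) and
a linear readout maps the top layer's hidden states to one predicted value
per time step; steps 2..T yield the 100-interval target curve when T = 101.
Training minimizes mean squared error by full backpropagation through time
with Adam, implemented directly in numpy so that runs are bit-reproducible
given a seed.

Waveform similarity between predicted and measured curves is scored with
the between-protocol coefficient of multiple correlation (CMC, two
protocols: predicted vs measured) and RMSE in min-max-scaled units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import substream
from .preprocessing import MinMaxStats

__all__ = [
    "LSTMCellParams",
    "LSTMCellState",
    "lstm_cell_step",
    "LSTMRegressor",
    "LSTMRunConfig",
    "default_run_config",
    "split_by_trial",
    "TrainedModel",
    "EvalMetrics",
    "train",
    "evaluate",
    "cmc",
    "cmc_detailed",
    "rmse",
]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


# --- reference cell -------------------------------------------------------

@dataclass
class LSTMCellParams:
    """Gate weights over the concatenated [h_{t-1}, x_t] vector."""

    W_f: np.ndarray
    W_i: np.ndarray
    W_C: np.ndarray
    W_o: np.ndarray
    b_f: np.ndarray
    b_i: np.ndarray
    b_C: np.ndarray
    b_o: np.ndarray

    def __post_init__(self) -> None:
        h = self.b_f.shape[0]
        for name in ("W_f", "W_i", "W_C", "W_o"):
            W = getattr(self, name)
            if W.ndim != 2 or W.shape[1] != h:
                raise ValueError(f"{name} must have shape (hidden+inputs, {h})")
        for name in ("b_i", "b_C", "b_o"):
            if getattr(self, name).shape != (h,):
                raise ValueError(f"{name} must have shape ({h},)")

    @property
    def hidden_size(self) -> int:
        return self.b_f.shape[0]

    @classmethod
    def zeros(cls, hidden: int, inputs: int) -> "LSTMCellParams":
        shape = (hidden + inputs, hidden)
        return cls(*(np.zeros(shape) for _ in range(4)),
                   *(np.zeros(hidden) for _ in range(4)))


@dataclass
class LSTMCellState:
    h: np.ndarray
    C: np.ndarray


def lstm_cell_step(params: LSTMCellParams, state: LSTMCellState,
                   x_t: np.ndarray) -> LSTMCellState:
    """One step of the gated recurrence (reference implementation).

    Operates on 1-D state/input vectors in float64; the batched training
    path in :class:`LSTMRegressor` is checked against this function.
    """
    xcat = np.concatenate([state.h, np.asarray(x_t, dtype=float)])
    if xcat.shape[0] != params.W_f.shape[0]:
        raise ValueError(
            f"[h, x] has length {xcat.shape[0]} but weights expect "
            f"{params.W_f.shape[0]}"
        )
    f = _sigmoid(xcat @ params.W_f + params.b_f)
    i = _sigmoid(xcat @ params.W_i + params.b_i)
    g = np.tanh(xcat @ params.W_C + params.b_C)
    C = f * state.C + i * g
    o = _sigmoid(xcat @ params.W_o + params.b_o)
    h = o * np.tanh(C)
    return LSTMCellState(h=h, C=C)


# --- stacked model --------------------------------------------------------

class LSTMRegressor:
    """Stack of LSTM layers plus a per-step linear readout.

    Internally each layer holds one combined weight matrix W of shape
    (hidden + inputs, 4 * hidden) with gate blocks ordered (f, i, o, C) so
    the three sigmoid gates form one contiguous block; the forget-gate bias
    is initialized to +1 (standard practice, keeps early cell-state
    gradients alive), other parameters Glorot-uniform.
    """

    def __init__(self, n_channels: int = 18, units: int = 100,
                 n_layers: int = 3, seed: int = 0,
                 dtype: np.dtype = np.float32, forget_bias: float = 1.0):
        self.n_channels = n_channels
        self.units = units
        self.n_layers = n_layers
        self.dtype = np.dtype(dtype)
        rng = substream(seed, "lstm-init")
        self.layers: list[dict[str, np.ndarray]] = []
        d_in = n_channels
        for _ in range(n_layers):
            fan_in = d_in + units
            limit = np.sqrt(6.0 / (fan_in + 4 * units))
            W = rng.uniform(-limit, limit, size=(fan_in, 4 * units))
            b = np.zeros(4 * units)
            b[:units] = forget_bias
            self.layers.append(
                {"W": W.astype(self.dtype), "b": b.astype(self.dtype)}
            )
            d_in = units
        limit = np.sqrt(6.0 / (units + 1))
        self.head_w = rng.uniform(-limit, limit, size=units).astype(self.dtype)
        self.head_b = np.zeros(1, dtype=self.dtype)

    # parameter plumbing ---------------------------------------------------
    def parameters(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            out += [layer["W"], layer["b"]]
        out += [self.head_w, self.head_b]
        return out

    def cell_params(self, layer: int) -> LSTMCellParams:
        """Expose one layer's weights in per-gate form (float64 copies)."""
        W = np.asarray(self.layers[layer]["W"], dtype=float)
        b = np.asarray(self.layers[layer]["b"], dtype=float)
        H = self.units
        return LSTMCellParams(
            W_f=W[:, :H], W_i=W[:, H:2 * H], W_o=W[:, 2 * H:3 * H],
            W_C=W[:, 3 * H:],
            b_f=b[:H], b_i=b[H:2 * H], b_o=b[2 * H:3 * H], b_C=b[3 * H:],
        )

    # forward --------------------------------------------------------------
    def _forward(self, X: np.ndarray, keep_cache: bool = False):
        X = np.asarray(X, dtype=self.dtype)
        if X.ndim != 3 or X.shape[2] != self.n_channels:
            raise ValueError(
                f"input must have shape (batch, T, {self.n_channels}); "
                f"got {X.shape}"
            )
        B, T, _ = X.shape
        H = self.units
        caches = []
        inp = X
        for layer in self.layers:
            W, b = layer["W"], layer["b"]
            h = np.zeros((B, H), dtype=self.dtype)
            c = np.zeros((B, H), dtype=self.dtype)
            H_seq = np.empty((B, T, H), dtype=self.dtype)
            steps = []
            for t in range(T):
                xcat = np.concatenate([h, inp[:, t, :]], axis=1)
                z = xcat @ W
                z += b
                # gate order (f, i, o, C): one sigmoid over the first 3H
                gates = z[:, :3 * H]
                np.negative(gates, out=gates)
                np.exp(gates, out=gates)
                gates += 1.0
                np.reciprocal(gates, out=gates)
                f = z[:, :H]
                i = z[:, H:2 * H]
                o = z[:, 2 * H:3 * H]
                g = np.tanh(z[:, 3 * H:])
                c_prev = c
                c = f * c_prev + i * g
                tanh_c = np.tanh(c)
                h = o * tanh_c
                H_seq[:, t, :] = h
                if keep_cache:
                    steps.append((xcat, f, i, g, o, c_prev, tanh_c))
            caches.append(steps)
            inp = H_seq
        outputs = inp @ self.head_w + self.head_b[0]  # (B, T)
        if keep_cache:
            return outputs, inp, caches
        return outputs

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Per-step readout for a batch of windows, shape (batch, T)."""
        return np.asarray(self._forward(X), dtype=float)

    def predict_curve(self, X: np.ndarray) -> np.ndarray:
        """Predicted target curve: readout at steps 2..T, shape (batch, T-1)."""
        return self.forward(X)[:, 1:]

    # backward -------------------------------------------------------------
    def _backward(self, X, outputs, H_top, caches, dY):
        """Gradients of a scalar loss with dL/doutputs = dY, matching
        :meth:`parameters` order."""
        B, T, _ = np.asarray(X).shape
        H = self.units
        dY = dY.astype(self.dtype)
        grads = [np.zeros_like(p) for p in self.parameters()]
        g_head_w, g_head_b = grads[-2], grads[-1]
        g_head_w += np.einsum("bt,bth->h", dY, H_top)
        g_head_b += dY.sum(keepdims=True).reshape(1)
        dH_above = dY[:, :, None] * self.head_w[None, None, :]

        for li in range(self.n_layers - 1, -1, -1):
            W = self.layers[li]["W"]
            steps = caches[li]
            gW, gb = grads[2 * li], grads[2 * li + 1]
            d_in = W.shape[0] - H
            dX_seq = np.empty((B, T, d_in), dtype=self.dtype)
            dh_next = np.zeros((B, H), dtype=self.dtype)
            dc_next = np.zeros((B, H), dtype=self.dtype)
            dz = np.empty((B, 4 * H), dtype=self.dtype)
            for t in range(T - 1, -1, -1):
                xcat, f, i, g, o, c_prev, tanh_c = steps[t]
                dh = dH_above[:, t, :] + dh_next
                dc = dc_next + dh * o * (1.0 - tanh_c * tanh_c)
                np.multiply(dc, c_prev, out=dz[:, :H])  # df
                np.multiply(dc, g, out=dz[:, H:2 * H])  # di
                np.multiply(dh, tanh_c, out=dz[:, 2 * H:3 * H])  # do
                gate_block = dz[:, :3 * H]
                fio = np.concatenate([f, i, o], axis=1)
                gate_block *= fio
                gate_block *= (1.0 - fio)
                np.multiply(dc, i, out=dz[:, 3 * H:])  # dg pre-activation
                dz[:, 3 * H:] *= (1.0 - g * g)
                gW += xcat.T @ dz
                gb += dz.sum(axis=0)
                dxcat = dz @ W.T
                dh_next = dxcat[:, :H]
                dX_seq[:, t, :] = dxcat[:, H:]
                dc_next = dc * f
            dH_above = dX_seq
        return grads

    def loss_and_grads(self, X: np.ndarray, Y: np.ndarray):
        """MSE over the 100-interval curve (readout steps 2..T) + gradients."""
        outputs, H_top, caches = self._forward(X, keep_cache=True)
        pred = outputs[:, 1:]
        resid = (pred - np.asarray(Y, dtype=self.dtype))
        loss = float(np.mean(resid.astype(np.float64) ** 2))
        dY = np.zeros_like(outputs)
        dY[:, 1:] = 2.0 * resid / resid.size
        grads = self._backward(X, outputs, H_top, caches, dY)
        return loss, grads


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(p.dtype)


# --- training -------------------------------------------------------------

@dataclass(frozen=True)
class LSTMRunConfig:
    """Per-direction architecture/training settings.

    Defaults follow one model per direction with 3 layers; units/epochs per
    direction are supplied by :func:`default_run_config`.
    """

    direction: int
    units: int = 100
    epochs: int = 600
    layers: int = 3
    batch_size: int = 1024
    learning_rate: float = 1e-3
    split: tuple[float, float, float] = (0.70, 0.20, 0.10)
    seed: int = 0
    window_len: int | None = 25
    window_stride: int = 1
    plateau_patience: int | None = None
    plateau_min_delta: float = 1e-6
    restore_best: bool = True
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if min(self.split) <= 0:
            raise ValueError("split fractions must be positive")
        if self.epochs < 1 or self.batch_size < 1 or self.layers < 1:
            raise ValueError("epochs, batch_size, layers must be >= 1")


_DIRECTION_DEFAULTS = {90: (100, 600), 135: (120, 700), 180: (120, 750)}


def default_run_config(direction: int, **overrides) -> LSTMRunConfig:
    """The per-direction defaults: 90 -> (100 units, 600 epochs),
    135 -> (120, 700), 180 -> (120, 750); batch 1024, learning rate 1e-3."""
    units, epochs = _DIRECTION_DEFAULTS[int(direction)]
    kwargs = dict(direction=int(direction), units=units, epochs=epochs)
    kwargs.update(overrides)
    return LSTMRunConfig(**kwargs)


def split_by_trial(n: int, split: tuple[float, float, float],
                   rng: np.random.Generator
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shuffled train/val/test trial indices.

    Train and validation sizes are floored; the remainder goes to the test
    partition (225 trials with a 70/20/10 split -> 157/45/23).
    """
    order = rng.permutation(n)
    n_train = int(np.floor(split[0] * n))
    n_val = int(np.floor(split[1] * n))
    n_test = n - n_train - n_val
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(f"a split partition is empty for n={n}")
    return (order[:n_train], order[n_train:n_train + n_val],
            order[n_train + n_val:])


@dataclass
class EvalMetrics:
    """Waveform agreement between predicted and measured curves."""

    cmc: float
    rmse: float
    flags: list[str] = field(default_factory=list)


@dataclass
class TrainedModel:
    model: LSTMRegressor
    config: LSTMRunConfig
    x_stats: MinMaxStats
    y_min: float
    y_max: float
    history: pd.DataFrame
    splits: dict[str, np.ndarray]

    def scale_x(self, X: np.ndarray) -> np.ndarray:
        span = self.x_stats.maximum - self.x_stats.minimum
        return (X - self.x_stats.minimum) / span

    def scale_y(self, Y: np.ndarray) -> np.ndarray:
        return (Y - self.y_min) / (self.y_max - self.y_min)

    def predict_scaled(self, X_raw: np.ndarray) -> np.ndarray:
        """Predicted target curves in min-max-scaled units.

        With windowed training the full curve is assembled by averaging the
        predictions of all sliding windows covering each frame interval.
        """
        Xs = self.scale_x(np.asarray(X_raw, dtype=float))
        wl = self.config.window_len
        T = Xs.shape[1]
        if wl is None or wl >= T:
            return self.model.predict_curve(Xs)
        return _predict_windowed(self.model, Xs, wl, self.config.window_stride)


def _window_starts(T: int, wl: int, stride: int) -> np.ndarray:
    return np.arange(0, T - wl + 1, stride)


def _predict_windowed(model: LSTMRegressor, Xs: np.ndarray, wl: int,
                      stride: int) -> np.ndarray:
    n, T, _ = Xs.shape
    starts = _window_starts(T, wl, stride)
    sums = np.zeros((n, T - 1))
    counts = np.zeros(T - 1)
    for s in starts:
        pred = model.predict_curve(Xs[:, s:s + wl, :])  # (n, wl-1)
        sums[:, s:s + wl - 1] += pred
        counts[s:s + wl - 1] += 1
    # trailing intervals not covered by any window start: extend with the
    # last window shifted flush to the end
    if counts[-1] == 0:
        s = T - wl
        pred = model.predict_curve(Xs[:, s:, :])
        sums[:, s:] += pred
        counts[s:] += 1
    return sums / counts


def train(config: LSTMRunConfig, X: np.ndarray, Y: np.ndarray) -> TrainedModel:
    """Train one direction model on (trials, T, 18) windows and
    (trials, T-1) target curves.

    The split is by trial (never by window) to avoid leakage; feature and
    target min-max statistics are fitted on the training partition only and
    applied unchanged to validation/test.  When ``window_len`` is shorter
    than the sequence, the training sample unit is a sliding window of the
    trial (all (trial, start) pairs of the train split are shuffled into
    minibatches of ``batch_size``); otherwise whole sequences are batched.
    Early stopping is disabled unless ``plateau_patience`` is set, in which
    case training stops once the validation loss has not improved by
    ``plateau_min_delta`` for that many consecutive epochs (but never
    before a quarter of the epoch budget).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 3 or X.shape[2] != 18:
        raise ValueError("X must have shape (trials, T, 18)")
    if Y.shape != (X.shape[0], X.shape[1] - 1):
        raise ValueError("Y must have shape (trials, T - 1)")

    rng = substream(config.seed, "split", config.direction)
    tr, va, te = split_by_trial(X.shape[0], config.split, rng)

    x_lo = X[tr].min(axis=(0, 1))
    x_hi = X[tr].max(axis=(0, 1))
    span = x_hi - x_lo
    if np.any(span <= 0):
        raise ValueError("constant feature channel in the training partition")
    y_lo = float(Y[tr].min())
    y_hi = float(Y[tr].max())
    if y_hi <= y_lo:
        raise ValueError("constant target in the training partition")
    stats = MinMaxStats(minimum=x_lo, maximum=x_hi)
    Xs = (X - x_lo) / span
    Ys = (Y - y_lo) / (y_hi - y_lo)

    model = LSTMRegressor(
        n_channels=18, units=config.units, n_layers=config.layers,
        seed=config.seed, dtype=np.dtype(config.dtype),
    )
    opt = _Adam(model.parameters(), lr=config.learning_rate)
    batch_rng = substream(config.seed, "batches", config.direction)

    T = X.shape[1]
    wl = config.window_len
    windowed = wl is not None and wl < T
    if windowed:
        starts = _window_starts(T, wl, config.window_stride)
        # sample units are (trial, window-start) pairs of the train split
        pairs = np.stack(
            [np.repeat(tr, len(starts)), np.tile(starts, len(tr))], axis=1
        )
        va_pairs = np.stack(
            [np.repeat(va, len(starts)), np.tile(starts, len(va))], axis=1
        )
        span = np.arange(wl)

        def batch_arrays(p):
            xb = Xs[p[:, 0, None], p[:, 1, None] + span[None, :], :]
            yb = Ys[p[:, 0, None], p[:, 1, None] + span[None, :-1]]
            return xb, yb

    rows = []
    best_val = np.inf
    best_params: list[np.ndarray] | None = None
    stale = 0
    min_epochs = max(1, config.epochs // 4)
    for epoch in range(1, config.epochs + 1):
        epoch_loss = 0.0
        n_batches = 0
        if windowed:
            order = batch_rng.permutation(len(pairs))
            for lo in range(0, len(pairs), config.batch_size):
                xb, yb = batch_arrays(pairs[order[lo:lo + config.batch_size]])
                loss, grads = model.loss_and_grads(xb, yb)
                opt.step(grads)
                epoch_loss += loss
                n_batches += 1
            val_loss = 0.0
            for lo in range(0, len(va_pairs), config.batch_size):
                xb, yb = batch_arrays(va_pairs[lo:lo + config.batch_size])
                pred = model.predict_curve(xb)
                val_loss += float(((pred - yb) ** 2).sum())
            val_loss /= va_pairs.shape[0] * (wl - 1)
        else:
            order = batch_rng.permutation(len(tr))
            for lo in range(0, len(tr), config.batch_size):
                idx = tr[order[lo:lo + config.batch_size]]
                loss, grads = model.loss_and_grads(Xs[idx], Ys[idx])
                opt.step(grads)
                epoch_loss += loss
                n_batches += 1
            val_pred = model.predict_curve(Xs[va])
            val_loss = float(np.mean((val_pred - Ys[va]) ** 2))
        rows.append(
            {"epoch": epoch, "train_loss": epoch_loss / n_batches,
             "val_loss": val_loss}
        )
        if val_loss < best_val - config.plateau_min_delta:
            best_val = val_loss
            stale = 0
            if config.restore_best:
                best_params = [p.copy() for p in model.parameters()]
        else:
            stale += 1
        if (config.plateau_patience is not None
                and stale >= config.plateau_patience
                and epoch >= min_epochs):
            break

    # keep the parameters of the best validation epoch, not the last one:
    # the held-out error fluctuates with the stopping point otherwise
    if config.restore_best and best_params is not None:
        for p, b in zip(model.parameters(), best_params):
            p[...] = b

    history = pd.DataFrame(rows)
    return TrainedModel(
        model=model, config=config, x_stats=stats, y_min=y_lo, y_max=y_hi,
        history=history,
        splits={"train": tr, "val": va, "test": te},
    )


def evaluate(trained: TrainedModel, X: np.ndarray, Y: np.ndarray,
             partition: str = "test") -> EvalMetrics:
    """CMC and RMSE of the model's predictions on one partition, in
    min-max-scaled target units."""
    idx = trained.splits[partition]
    pred = trained.predict_scaled(np.asarray(X, dtype=float)[idx])
    meas = trained.scale_y(np.asarray(Y, dtype=float)[idx])
    value, flag = cmc_detailed(pred, meas)
    flags = [flag] if flag else []
    return EvalMetrics(cmc=value, rmse=rmse(pred, meas), flags=flags)


# --- metrics --------------------------------------------------------------

def cmc_detailed(predicted: np.ndarray, measured: np.ndarray
                 ) -> tuple[float, str | None]:
    """Between-protocol coefficient of multiple correlation, P = 2.

    CMC = sqrt(1 - [sum_f sum_p (Y_pf - Ybar_f)^2 / (F (P-1))]
                 / [sum_f sum_p (Y_pf - Ybar)^2 / (P F - 1)])

    where the two protocols are the predicted and measured curves and f
    runs over every (curve, frame) pair.  A negative radicand (prediction
    worse than the grand mean) is clipped to 0 and flagged; two identical
    constant curves are defined as CMC 1 and flagged degenerate.
    """
    p = np.atleast_2d(np.asarray(predicted, dtype=float))
    m = np.atleast_2d(np.asarray(measured, dtype=float))
    if p.shape != m.shape:
        raise ValueError("predicted and measured must share a shape")
    Y = np.stack([p.ravel(), m.ravel()])  # (2, F)
    P, F = Y.shape
    frame_mean = Y.mean(axis=0)
    within = ((Y - frame_mean) ** 2).sum() / (F * (P - 1))
    grand = Y.mean()
    total = ((Y - grand) ** 2).sum() / (P * F - 1)
    if total <= 1e-15 * (1.0 + grand**2):
        return 1.0, "degenerate: zero total variance"
    radicand = 1.0 - within / total
    if radicand < 0.0:
        return 0.0, "clipped: negative radicand"
    return float(np.sqrt(radicand)), None


def cmc(predicted: np.ndarray, measured: np.ndarray) -> float:
    return cmc_detailed(predicted, measured)[0]


def rmse(predicted: np.ndarray, measured: np.ndarray) -> float:
    """Root mean square error between curves of equal shape."""
    p = np.asarray(predicted, dtype=float)
    m = np.asarray(measured, dtype=float)
    if p.shape != m.shape:
        raise ValueError("predicted and measured must share a shape")
    return float(np.sqrt(np.mean((p - m) ** 2)))


# --- checkpointing --------------------------------------------------------

def save_checkpoint(trained: TrainedModel, path: str | Path) -> None:
    """Write model weights (.npz) plus a JSON manifest next to it."""
    path = Path(path)
    arrays = {}
    for i, layer in enumerate(trained.model.layers):
        arrays[f"W{i}"] = layer["W"]
        arrays[f"b{i}"] = layer["b"]
    arrays["head_w"] = trained.model.head_w
    arrays["head_b"] = trained.model.head_b
    arrays["x_min"] = trained.x_stats.minimum
    arrays["x_max"] = trained.x_stats.maximum
    np.savez(path, **arrays)
    manifest = {
        "direction": trained.config.direction,
        "units": trained.config.units,
        "layers": trained.config.layers,
        "seed": trained.config.seed,
        "epochs_run": int(trained.history["epoch"].max()),
        "y_min": trained.y_min,
        "y_max": trained.y_max,
    }
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))
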