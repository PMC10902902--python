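"""LSTM forecasting network with digital training and memristive inference.

The cell follows the standard gate equations

    f_t = sigmoid(W_xf x_t + W_hf h_{t-1} + b_f)      (forget)
    i_t = sigmoid(W_xi x_t + W_hi h_{t-1} + b_i)      (input)
    g_t = tanh   (W_xg x_t + W_hg h_{t-1} + b_g)      (candidate)
    c_t = f_t * c_{t-1} + i_t * g_t                   (long-term memory)
    o_t = sigmoid(W_xo x_t + W_ho h_{t-1} + b_o)      (output)
    h_t = o_t * tanh(c_t)                             (short-term memory)

Note the output gate conditions on h_{t-1}: conditioning it on h_t would
be circular, and the recurrence pattern of the other three gates fixes
the convention.

The network is input-projection (scalar -> feature space, default 100
dims) -> two stacked LSTM layers -> linear output projection to one
scalar.  Training is full backpropagation through time against the MSE
loss with Adam updates; gradients are hand-derived (and checked against
finite differences in the test suite).  For hardware emulation every
weight matrix can be programmed once into a differential memristive
crossbar; forward passes then route all matrix products through
:func:`memlstm.crossbar.vmm` while biases and activations stay digital.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
from scipy.special import expit as _sigmoid

from . import crossbar as xb
from .errors import DivergenceError, InvalidInputError, ShapeError
from .signalprep import WindowedDataset

_GATES = ("f", "i", "g", "o")


# ---------------------------------------------------------------------------
# parameter containers


@dataclass
class LSTMCellParams:
    """Gate weight matrices (hidden x input / hidden x hidden) and biases."""

    W_xf: np.ndarray
    W_hf: np.ndarray
    W_xi: np.ndarray
    W_hi: np.ndarray
    W_xg: np.ndarray
    W_hg: np.ndarray
    W_xo: np.ndarray
    W_ho: np.ndarray
    b_f: np.ndarray
    b_i: np.ndarray
    b_g: np.ndarray
    b_o: np.ndarray

    def __post_init__(self) -> None:
        h, d = self.W_xf.shape
        for g in _GATES:
            if getattr(self, f"W_x{g}").shape != (h, d):
                raise ShapeError("x-side gate matrices must share shape")
            if getattr(self, f"W_h{g}").shape != (h, h):
                raise ShapeError("h-side gate matrices must be hidden x hidden")
            if getattr(self, f"b_{g}").shape != (h,):
                raise ShapeError("biases must match the hidden dimension")

    @property
    def hidden(self) -> int:
        return self.W_xf.shape[0]

    @property
    def input_dim(self) -> int:
        return self.W_xf.shape[1]


@dataclass
class CellState:
    """Short-term (h) and long-term (c) memory vectors of one cell."""

    h: np.ndarray
    c: np.ndarray

    def __post_init__(self) -> None:
        if self.h.shape != self.c.shape:
            raise ShapeError("h and c must have equal shape")

    @classmethod
    def zeros(cls, hidden: int, batch: int | None = None) -> "CellState":
        shape = (hidden,) if batch is None else (batch, hidden)
        return cls(h=np.zeros(shape), c=np.zeros(shape))


@dataclass
class LSTMNetworkParams:
    """Full parameter stack: input projection, two cells, output projection."""

    W_in: np.ndarray   # (feature_dim, 1)
    b_in: np.ndarray   # (feature_dim,)
    cell1: LSTMCellParams
    cell2: LSTMCellParams
    W_out: np.ndarray  # (1, hidden2)
    b_out: np.ndarray  # (1,)

    def __post_init__(self) -> None:
        f = self.W_in.shape[0]
        if self.W_in.shape != (f, 1) or self.b_in.shape != (f,):
            raise ShapeError("input projection must map a scalar to features")
        if self.cell1.input_dim != f:
            raise ShapeError("cell1 input dim must equal the feature dim")
        if self.cell2.input_dim != self.cell1.hidden:
            raise ShapeError("cell2 input dim must equal cell1 hidden dim")
        if self.W_out.shape != (1, self.cell2.hidden) or self.b_out.shape != (1,):
            raise ShapeError("output projection must map hidden2 to a scalar")

    # flat views used by the optimizer and the checkpoint format -----------
    def as_dict(self) -> dict[str, np.ndarray]:
        out = {"in/W": self.W_in, "in/b": self.b_in,
               "out/W": self.W_out, "out/b": self.b_out}
        for tag, cell in (("c1", self.cell1), ("c2", self.cell2)):
            for g in _GATES:
                out[f"{tag}/W_x{g}"] = getattr(cell, f"W_x{g}")
                out[f"{tag}/W_h{g}"] = getattr(cell, f"W_h{g}")
                out[f"{tag}/b_{g}"] = getattr(cell, f"b_{g}")
        return out

    @classmethod
    def from_dict(cls, d: dict[str, np.ndarray]) -> "LSTMNetworkParams":
        def cell(tag):
            kw = {}
            for g in _GATES:
                kw[f"W_x{g}"] = d[f"{tag}/W_x{g}"]
                kw[f"W_h{g}"] = d[f"{tag}/W_h{g}"]
                kw[f"b_{g}"] = d[f"{tag}/b_{g}"]
            return LSTMCellParams(**kw)

        return cls(W_in=d["in/W"], b_in=d["in/b"], cell1=cell("c1"),
                   cell2=cell("c2"), W_out=d["out/W"], b_out=d["out/b"])


def init_params(
    feature_dim: int = 100,
    hidden: int = 100,
    seed: int = 0,
) -> LSTMNetworkParams:
    """Seeded uniform +-1/sqrt(fan_in) initialization of all parameters."""
    rng = np.random.default_rng(seed)

    def u(shape, fan_in):
        bound = 1.0 / np.sqrt(fan_in)
        return rng.uniform(-bound, bound, shape)

    def cell(input_dim, h):
        kw = {}
        for g in _GATES:
            kw[f"W_x{g}"] = u((h, input_dim), input_dim)
            kw[f"W_h{g}"] = u((h, h), h)
            kw[f"b_{g}"] = np.zeros(h)
        return LSTMCellParams(**kw)

    return LSTMNetworkParams(
        W_in=u((feature_dim, 1), 1),
        b_in=np.zeros(feature_dim),
        cell1=cell(feature_dim, hidden),
        cell2=cell(hidden, hidden),
        W_out=u((1, hidden), hidden),
        b_out=np.zeros(1),
    )


# ---------------------------------------------------------------------------
# forward passes


def cell_forward(x, state: CellState, params: LSTMCellParams):
    """One LSTM step.  Returns (new state, gate activations dict).

    ``x`` may be a vector (input_dim,) or a batch (B, input_dim); the
    state shape must match.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != params.input_dim:
        raise ShapeError(
            f"input dim {x.shape[-1]} != cell input dim {params.input_dim}"
        )
    h_prev, c_prev = state.h, state.c
    f = _sigmoid(x @ params.W_xf.T + h_prev @ params.W_hf.T + params.b_f)
    i = _sigmoid(x @ params.W_xi.T + h_prev @ params.W_hi.T + params.b_i)
    g = np.tanh(x @ params.W_xg.T + h_prev @ params.W_hg.T + params.b_g)
    o = _sigmoid(x @ params.W_xo.T + h_prev @ params.W_ho.T + params.b_o)
    c = f * c_prev + i * g
    h = o * np.tanh(c)
    return CellState(h=h, c=c), {"f": f, "i": i, "g": g, "o": o}


def network_forward(window, params: LSTMNetworkParams) -> float:
    """Scalar forecast from one input window (zero-initialized states)."""
    window = np.asarray(window, dtype=float).ravel()
    if window.size == 0:
        raise InvalidInputError("input window must be non-empty")
    return float(_forward_batch(params, window[None, :])[0])


def _forward_batch(params: LSTMNetworkParams, X: np.ndarray,
                   cache: list | None = None) -> np.ndarray:
    """Batched forward over windows X (B, L); optionally fills a BPTT cache."""
    B, L = X.shape
    s1 = CellState.zeros(params.cell1.hidden, B)
    s2 = CellState.zeros(params.cell2.hidden, B)
    for t in range(L):
        u = X[:, t: t + 1] @ params.W_in.T + params.b_in
        prev1, prev2 = s1, s2
        s1, gates1 = cell_forward(u, s1, params.cell1)
        s2, gates2 = cell_forward(s1.h, s2, params.cell2)
        if cache is not None:
            cache.append((u, prev1, gates1, s1, prev2, gates2, s2))
    return s2.h @ params.W_out[0] + params.b_out[0]


# ---------------------------------------------------------------------------
# gradients (BPTT) and training


def _zeros_like_params(params: LSTMNetworkParams) -> dict[str, np.ndarray]:
    return {k: np.zeros_like(v) for k, v in params.as_dict().items()}


def _cell_backward(dh, dc_in, x, prev: CellState, gates, new: CellState,
                   p: LSTMCellParams, grads, tag):
    """Backward through one LSTM step; returns (dx, dh_prev, dc_prev)."""
    f, i, g, o = gates["f"], gates["i"], gates["g"], gates["o"]
    tc = np.tanh(new.c)
    dc = dh * o * (1.0 - tc**2) + dc_in
    dz = {
        "o": dh * tc * o * (1.0 - o),
        "f": dc * prev.c * f * (1.0 - f),
        "i": dc * g * i * (1.0 - i),
        "g": dc * i * (1.0 - g**2),
    }
    dx = np.zeros_like(x)
    dh_prev = np.zeros_like(dh)
    for name, d in dz.items():
        grads[f"{tag}/W_x{name}"] += d.T @ x
        grads[f"{tag}/W_h{name}"] += d.T @ prev.h
        grads[f"{tag}/b_{name}"] += d.sum(axis=0)
        dx += d @ getattr(p, f"W_x{name}")
        dh_prev += d @ getattr(p, f"W_h{name}")
    return dx, dh_prev, dc * f


def mse_loss_and_grads(params: LSTMNetworkParams, X: np.ndarray, y: np.ndarray):
    """MSE loss over a window batch and its gradient for every parameter.

    Returns ``(loss, grads)`` with ``grads`` keyed like
    :meth:`LSTMNetworkParams.as_dict`.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    B, L = X.shape
    cache: list = []
    yhat = _forward_batch(params, X, cache=cache)
    resid = yhat - y
    loss = float(np.mean(resid**2))

    grads = _zeros_like_params(params)
    dyhat = 2.0 * resid / B
    h2_final = cache[-1][6].h
    grads["out/W"][0] += dyhat @ h2_final
    grads["out/b"][0] += dyhat.sum()
    dh2 = np.outer(dyhat, params.W_out[0])
    dc2 = np.zeros_like(dh2)
    dh1 = np.zeros((B, params.cell1.hidden))
    dc1 = np.zeros_like(dh1)
    for t in range(L - 1, -1, -1):
        u, prev1, gates1, new1, prev2, gates2, new2 = cache[t]
        dx2, dh2, dc2 = _cell_backward(
            dh2, dc2, new1.h, prev2, gates2, new2, params.cell2, grads, "c2"
        )
        dx1, dh1, dc1 = _cell_backward(
            dh1 + dx2, dc1, u, prev1, gates1, new1, params.cell1, grads, "c1"
        )
        grads["in/W"][:, 0] += dx1.T @ X[:, t]
        grads["in/b"] += dx1.sum(axis=0)
    return loss, grads


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters (none are stated by the source study)."""

    lr: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 500
    patience: int = 10          # early-stopping patience, epochs
    val_fraction: float = 0.1   # chronological tail of the training windows
    clip_norm: float = 5.0      # global gradient-norm clip; 0 disables
    feature_dim: int = 100
    hidden: int = 100


class LSTMNetwork:
    """A trained (or freshly initialized) digital forecasting network."""

    def __init__(self, params: LSTMNetworkParams):
        self.params = params

    def predict(self, window) -> float:
        return network_forward(window, self.params)

    def predict_batch(self, windows: np.ndarray) -> np.ndarray:
        return _forward_batch(self.params, np.atleast_2d(np.asarray(windows, float)))

    # checkpointing --------------------------------------------------------
    def save(self, path: str | Path, seed: int | None = None,
             extra_meta: dict | None = None) -> None:
        """HDF5 archive of named arrays plus a JSON metadata sidecar."""
        path = Path(path)
        flat = self.params.as_dict()
        with h5py.File(path, "w") as fh:
            for k, v in flat.items():
                fh[k] = v
        meta = {
            "feature_dim": int(self.params.W_in.shape[0]),
            "hidden1": int(self.params.cell1.hidden),
            "hidden2": int(self.params.cell2.hidden),
            "seed": seed,
            "config_hash": hashlib.sha256(
                b"".join(flat[k].tobytes() for k in sorted(flat))
            ).hexdigest()[:16],
        }
        if extra_meta:
            meta.update(extra_meta)
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(meta, indent=2)
        )

    @classmethod
    def load(cls, path: str | Path) -> "LSTMNetwork":
        with h5py.File(path, "r") as fh:
            flat = {}
            fh.visititems(
                lambda name, obj: flat.__setitem__(name, obj[()])
                if isinstance(obj, h5py.Dataset) else None
            )
        return cls(LSTMNetworkParams.from_dict(flat))


class PersistenceForecaster:
    """Baseline that forecasts the last observed value of the window."""

    def predict(self, window) -> float:
        return float(np.asarray(window).ravel()[-1])

    def predict_batch(self, windows: np.ndarray) -> np.ndarray:
        return np.atleast_2d(np.asarray(windows, float))[:, -1].copy()


def train(
    dataset: WindowedDataset,
    hyper: TrainConfig = TrainConfig(),
    seed: int = 0,
) -> tuple[LSTMNetwork, dict]:
    """Fit the network by BPTT + Adam on MSE; returns (network, history).

    The last ``val_fraction`` of the training windows (chronological tail)
    is held out for early stopping; the best-validation parameters are
    restored.  History records per-epoch train and validation loss.
    Fully deterministic for a fixed seed.
    """
    if len(dataset) == 0:
        raise InvalidInputError("training dataset is empty")
    X, y = dataset.inputs, dataset.targets
    n_val = int(round(hyper.val_fraction * len(y)))
    n_val = min(max(n_val, 1), len(y) - 1) if len(y) > 1 else 0
    X_tr, y_tr = X[: len(y) - n_val], y[: len(y) - n_val]
    X_val, y_val = X[len(y) - n_val:], y[len(y) - n_val:]

    params = init_params(hyper.feature_dim, hyper.hidden, seed=seed)
    flat = {k: v.copy() for k, v in params.as_dict().items()}
    params = LSTMNetworkParams.from_dict(flat)
    m = {k: np.zeros_like(v) for k, v in flat.items()}
    v2 = {k: np.zeros_like(v) for k, v in flat.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    rng = np.random.default_rng(seed + 1)
    history = {"train_loss": [], "val_loss": []}
    best_val, best_flat, stale, step = np.inf, None, 0, 0

    for epoch in range(hyper.max_epochs):
        order = rng.permutation(len(y_tr))
        epoch_loss = 0.0
        for start in range(0, len(order), hyper.batch_size):
            idx = order[start: start + hyper.batch_size]
            loss, grads = mse_loss_and_grads(params, X_tr[idx], y_tr[idx])
            if not np.isfinite(loss):
                raise DivergenceError(
                    "training loss is non-finite; lower the learning rate"
                )
            if hyper.clip_norm > 0:
                norm = np.sqrt(sum(float(np.sum(g**2)) for g in grads.values()))
                if norm > hyper.clip_norm:
                    grads = {k: g * (hyper.clip_norm / norm)
                             for k, g in grads.items()}
            step += 1
            for k in flat:
                m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
                v2[k] = beta2 * v2[k] + (1 - beta2) * grads[k] ** 2
                mhat = m[k] / (1 - beta1**step)
                vhat = v2[k] / (1 - beta2**step)
                flat[k] -= hyper.lr * mhat / (np.sqrt(vhat) + eps)
            epoch_loss += loss * len(idx)
        history["train_loss"].append(epoch_loss / len(y_tr))

        if n_val:
            val_pred = _forward_batch(params, X_val)
            val_loss = float(np.mean((val_pred - y_val) ** 2))
        else:
            val_loss = history["train_loss"][-1]
        history["val_loss"].append(val_loss)
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_flat = {k: w.copy() for k, w in flat.items()}
            stale = 0
        else:
            stale += 1
            if stale >= hyper.patience:
                break

    if best_flat is not None:
        flat = best_flat
    return LSTMNetwork(LSTMNetworkParams.from_dict(flat)), history


# ---------------------------------------------------------------------------
# memristive inference


@dataclass(frozen=True)
class XbarConfig:
    """Programming settings applied to every weight matrix."""

    g_min: float = 1e-5
    g_max: float = 1e-4
    levels: int | None = 256
    noise_sigma: float = 0.0
    seed: int | None = None


class MemristiveLSTMNetwork:
    """Inference-only network whose matrix products run on crossbars.

    Each weight matrix W is programmed as W.T so that driving the rows
    with the activation vector yields W @ x on the columns.  Biases and
    the nonlinear activations remain digital, mirroring a mixed-signal
    design where sigmoid/tanh stages follow the analog array.
    """

    def __init__(self, crossbars: dict[str, xb.CrossbarArray],
                 biases: dict[str, np.ndarray]):
        self.crossbars = crossbars
        self.biases = biases

    def predict(self, window) -> float:
        return float(self.predict_batch(np.asarray(window, float)[None, :])[0])

    def predict_batch(self, windows: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(windows, dtype=float))
        B, L = X.shape
        lin = lambda name, V: xb.vmm(self.crossbars[name], V)
        h1 = np.zeros((B, self.biases["c1/b_f"].shape[0]))
        c1 = np.zeros_like(h1)
        h2 = np.zeros((B, self.biases["c2/b_f"].shape[0]))
        c2 = np.zeros_like(h2)
        for t in range(L):
            u = lin("in/W", X[:, t: t + 1]) + self.biases["in/b"]
            h1, c1 = self._cell_step(u, h1, c1, "c1", lin)
            h2, c2 = self._cell_step(h1, h2, c2, "c2", lin)
        return lin("out/W", h2)[:, 0] + self.biases["out/b"][0]

    def _cell_step(self, x, h_prev, c_prev, tag, lin):
        b = self.biases
        f = _sigmoid(lin(f"{tag}/W_xf", x) + lin(f"{tag}/W_hf", h_prev) + b[f"{tag}/b_f"])
        i = _sigmoid(lin(f"{tag}/W_xi", x) + lin(f"{tag}/W_hi", h_prev) + b[f"{tag}/b_i"])
        g = np.tanh(lin(f"{tag}/W_xg", x) + lin(f"{tag}/W_hg", h_prev) + b[f"{tag}/b_g"])
        o = _sigmoid(lin(f"{tag}/W_xo", x) + lin(f"{tag}/W_ho", h_prev) + b[f"{tag}/b_o"])
        c = f * c_prev + i * g
        return o * np.tanh(c), c


def to_memristive(
    network: LSTMNetwork | LSTMNetworkParams,
    config: XbarConfig = XbarConfig(),
) -> MemristiveLSTMNetwork:
    """Program every weight matrix of a trained network into a crossbar.

    Weight matrices (input projection, the eight gate matrices of each
    cell, output projection) are each mapped onto one differential
    array; biases stay digital.  With continuous noiseless crossbars the
    memristive forward equals the digital forward to floating precision.
    """
    params = network.params if isinstance(network, LSTMNetwork) else network
    crossbars: dict[str, xb.CrossbarArray] = {}
    biases: dict[str, np.ndarray] = {}
    base_seed = config.seed
    for k, arr in params.as_dict().items():
        if "/b" in k:
            biases[k] = arr.copy()
            continue
        seed = None
        if config.noise_sigma > 0:
            if base_seed is None:
                raise InvalidInputError("XbarConfig.seed required with noise")
            # distinct stream per matrix, deterministic in the base seed
            h = hashlib.sha256(f"{base_seed}:{k}".encode()).digest()
            seed = int.from_bytes(h[:4], "big") % (2**31 - 1)
        crossbars[k] = xb.program_weights(
            arr.T,  # rows driven by the activation vector
            g_min=config.g_min, g_max=config.g_max,
            levels=config.levels, noise_sigma=config.noise_sigma, seed=seed,
        )
    return MemristiveLSTMNetwork(crossbars, biases)
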