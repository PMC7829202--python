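"""Trainable LSTM/BiLSTM per-sample sequence classifier.

A stack of 1-5 recurrent layers (unidirectional or bidirectional) maps the
321-sample normalized ABR window to per-step class logits through a shared
affine head; a two-class softmax gives each sample's probability of being
a characteristic-wave feature point.  Training minimizes the mean per-step
cross-entropy over sweeps with Adam.

Everything — forward pass, backpropagation through time, the optimizer —
is implemented directly on numpy arrays.  Gates are stored in a single
fused weight matrix per direction (order: input, forget, candidate,
output) so each time step costs one GEMM; correctness of both the forward
recursion (against the per-gate reference cell) and the hand-derived
gradients (against central finite differences) is pinned by the test
suite.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from ..core import WINDOW_LEN
from ..labelgen import LabelVector, WindowedTrace, normalize_trace
from .reference import LstmCellParams

__all__ = [
    "SequenceModelConfig",
    "SequenceModel",
    "TrainingLog",
    "build_model",
    "train",
    "predict_probs",
    "save_model",
    "load_model",
]

_GATES = 4  # i, f, g, o


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass(frozen=True)
class SequenceModelConfig:
    """Architecture + optimization hyperparameters.

    The seven benchmark structures (LSTM, LSTMx2, BiLSTM, BiLSTMx2..x5)
    correspond to ``directionality`` in {"uni", "bi"} with 1-5 layers;
    ``hidden_nodes`` is typically one of 64/128/256/512 (default 512).
    Optimizer defaults — Adam, lr 1e-3, 60 epochs, batch 32 — are standard
    stable choices for recurrent nets of this size.
    """

    directionality: str = "bi"
    num_layers: int = 3
    hidden_nodes: int = 512
    learning_rate: float = 1e-3
    epochs: int = 60
    batch_size: int = 32
    val_fraction: float = 0.1
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.directionality not in ("uni", "bi"):
            raise ValueError("directionality must be 'uni' or 'bi'")
        if not 1 <= self.num_layers <= 5:
            raise ValueError("num_layers must be 1..5")
        if self.hidden_nodes < 1:
            raise ValueError("hidden_nodes must be positive")
        if self.dtype not in ("float32", "float64"):
            raise ValueError("dtype must be float32 or float64")

    @property
    def name(self) -> str:
        base = "BiLSTM" if self.directionality == "bi" else "LSTM"
        return base if self.num_layers == 1 else f"{base}x{self.num_layers}"


class _Direction:
    """One recurrence direction of one layer: fused weights and BPTT."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator, dtype):
        k = 1.0 / np.sqrt(hidden)
        self.Wx = rng.uniform(-k, k, (d_in, _GATES * hidden)).astype(dtype)
        self.Wh = rng.uniform(-k, k, (hidden, _GATES * hidden)).astype(dtype)
        self.b = rng.uniform(-k, k, _GATES * hidden).astype(dtype)
        self.b[hidden : 2 * hidden] += 1.0  # forget-gate bias: remember by default
        self.hidden = hidden
        self.d_in = d_in

    def forward(self, X: np.ndarray, reverse: bool, cache: bool = False):
        T, B, _ = X.shape
        H = self.hidden
        Zx = X.reshape(T * B, -1) @ self.Wx
        Zx = Zx.reshape(T, B, _GATES * H)
        h = np.zeros((B, H), dtype=X.dtype)
        c = np.zeros((B, H), dtype=X.dtype)
        steps = range(T - 1, -1, -1) if reverse else range(T)
        Hs = np.empty((T, B, H), dtype=X.dtype)
        if cache:
            G = np.empty((T, B, _GATES * H), dtype=X.dtype)
            Cprev = np.empty((T, B, H), dtype=X.dtype)
            TC = np.empty((T, B, H), dtype=X.dtype)
            Hprev = np.empty((T, B, H), dtype=X.dtype)
        for t in steps:
            z = Zx[t] + h @ self.Wh + self.b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            if cache:
                Hprev[t] = h
                Cprev[t] = c
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            Hs[t] = h
            if cache:
                G[t, :, :H] = i
                G[t, :, H : 2 * H] = f
                G[t, :, 2 * H : 3 * H] = g
                G[t, :, 3 * H :] = o
                TC[t] = tc
        if cache:
            self._cache = (X, G, Cprev, TC, Hprev, reverse)
        return Hs

    def backward(self, dH: np.ndarray):
        """Given loss gradient w.r.t. this direction's outputs, return the
        gradient w.r.t. the layer input and accumulate parameter grads."""
        X, G, Cprev, TC, Hprev, reverse = self._cache
        T, B, _ = X.shape
        H = self.hidden
        dZ = np.empty_like(G)
        dh_next = np.zeros((B, H), dtype=X.dtype)
        dc_next = np.zeros((B, H), dtype=X.dtype)
        steps = range(T) if reverse else range(T - 1, -1, -1)
        for t in steps:
            i = G[t, :, :H]
            f = G[t, :, H : 2 * H]
            g = G[t, :, 2 * H : 3 * H]
            o = G[t, :, 3 * H :]
            tc = TC[t]
            dh = dH[t] + dh_next
            dc = dc_next + dh * o * (1.0 - tc * tc)
            do = dh * tc
            di = dc * g
            dg = dc * i
            df = dc * Cprev[t]
            dc_next = dc * f
            dz = dZ[t]
            dz[:, :H] = di * i * (1.0 - i)
            dz[:, H : 2 * H] = df * f * (1.0 - f)
            dz[:, 2 * H : 3 * H] = dg * (1.0 - g * g)
            dz[:, 3 * H :] = do * o * (1.0 - o)
            dh_next = dz @ self.Wh.T
        flatZ = dZ.reshape(T * B, -1)
        self.dWx = X.reshape(T * B, -1).T @ flatZ
        self.dWh = Hprev.reshape(T * B, -1).T @ flatZ
        self.db = flatZ.sum(axis=0)
        dX = (flatZ @ self.Wx.T).reshape(X.shape)
        self._cache = None
        return dX

    def params(self) -> dict[str, np.ndarray]:
        return {"Wx": self.Wx, "Wh": self.Wh, "b": self.b}

    def grads(self) -> dict[str, np.ndarray]:
        return {"Wx": self.dWx, "Wh": self.dWh, "b": self.db}

    def as_cell_params(self) -> LstmCellParams:
        """Export the fused weights in per-gate reference-cell layout."""
        H = self.hidden
        sl = {"i": slice(0, H), "f": slice(H, 2 * H), "a": slice(2 * H, 3 * H),
              "o": slice(3 * H, 4 * H)}
        kw = {}
        for gate, s in sl.items():
            kw[f"W_{gate}"] = np.asarray(self.Wh[:, s].T, dtype=float)
            kw[f"U_{gate}"] = np.asarray(self.Wx[:, s].T, dtype=float)
            kw[f"b_{gate}"] = np.asarray(self.b[s], dtype=float)
        return LstmCellParams(**kw)


class _Layer:
    """Uni- or bidirectional recurrent layer (outputs concatenated)."""

    def __init__(self, d_in, hidden, bidirectional, rng, dtype):
        self.bidirectional = bidirectional
        self.fw = _Direction(d_in, hidden, rng, dtype)
        self.bw = _Direction(d_in, hidden, rng, dtype) if bidirectional else None

    @property
    def d_out(self) -> int:
        return self.fw.hidden * (2 if self.bidirectional else 1)

    def forward(self, X, cache=False):
        Hf = self.fw.forward(X, reverse=False, cache=cache)
        if not self.bidirectional:
            return Hf
        Hb = self.bw.forward(X, reverse=True, cache=cache)
        return np.concatenate([Hf, Hb], axis=2)

    def backward(self, dH):
        if not self.bidirectional:
            return self.fw.backward(dH)
        H = self.fw.hidden
        dX = self.fw.backward(dH[:, :, :H])
        dX += self.bw.backward(dH[:, :, H:])
        return dX

    def directions(self):
        return [self.fw] + ([self.bw] if self.bidirectional else [])


class SequenceModel:
    """Stacked recurrent layers plus a shared per-step affine-softmax head."""

    def __init__(self, config: SequenceModelConfig):
        self.config = config
        dtype = np.dtype(config.dtype)
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
        self.layers: list[_Layer] = []
        d_in = 1
        for _ in range(config.num_layers):
            layer = _Layer(d_in, config.hidden_nodes,
                           config.directionality == "bi", rng, dtype)
            self.layers.append(layer)
            d_in = layer.d_out
        k = 1.0 / np.sqrt(d_in)
        self.V = rng.uniform(-k, k, (d_in, 2)).astype(dtype)
        self.c = np.zeros(2, dtype=dtype)

    # -- forward / backward -------------------------------------------------
    def logits(self, X: np.ndarray, cache: bool = False) -> np.ndarray:
        """X: (T, B, 1) normalized potentials -> (T, B, 2) logits."""
        H = X
        for layer in self.layers:
            H = layer.forward(H, cache=cache)
        if cache:
            self._head_in = H
        T, B, _ = H.shape
        return (H.reshape(T * B, -1) @ self.V + self.c).reshape(T, B, 2)

    def backward(self, dlogits: np.ndarray) -> None:
        T, B, _ = dlogits.shape
        flat = dlogits.reshape(T * B, 2)
        Hin = self._head_in.reshape(T * B, -1)
        self.dV = Hin.T @ flat
        self.dc = flat.sum(axis=0)
        dH = (flat @ self.V.T).reshape(self._head_in.shape)
        for layer in reversed(self.layers):
            dH = layer.backward(dH)
        self._head_in = None

    # -- parameter bookkeeping ---------------------------------------------
    def parameters(self) -> dict[str, np.ndarray]:
        out = {"head.V": self.V, "head.c": self.c}
        for li, layer in enumerate(self.layers):
            for di, d in enumerate(layer.directions()):
                for k, v in d.params().items():
                    out[f"layer{li}.dir{di}.{k}"] = v
        return out

    def gradients(self) -> dict[str, np.ndarray]:
        out = {"head.V": self.dV, "head.c": self.dc}
        for li, layer in enumerate(self.layers):
            for di, d in enumerate(layer.directions()):
                for k, v in d.grads().items():
                    out[f"layer{li}.dir{di}.{k}"] = v
        return out


def build_model(config: SequenceModelConfig) -> SequenceModel:
    """Instantiate a model with seeded initial parameters."""
    return SequenceModel(config)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def sequence_loss_and_grad(
    model: SequenceModel, X: np.ndarray, Y: np.ndarray, compute_grad: bool = True
) -> float:
    """Mean per-step two-class cross-entropy over a batch.

    X: (T, B, 1) inputs, Y: (T, B) integer targets.  When ``compute_grad``
    the parameter gradients are left on the model.
    """
    logits = model.logits(X, cache=compute_grad)
    P = softmax(logits)
    T, B = Y.shape
    eps = np.finfo(P.dtype).tiny
    picked = np.take_along_axis(P, Y[..., None], axis=2)[..., 0]
    loss = float(-np.log(np.maximum(picked, eps)).mean())
    if compute_grad:
        onehot = np.zeros_like(P)
        np.put_along_axis(onehot, Y[..., None], 1.0, axis=2)
        model.backward((P - onehot) / (T * B))
    return loss


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for k, p in params.items():
            g = grads[k]
            m = self.m[k]
            v = self.v[k]
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)


@dataclass
class TrainingLog:
    """Per-epoch loss trajectory of one training run."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    config: SequenceModelConfig | None = None

    @property
    def final_train_loss(self) -> float:
        return self.train_loss[-1]

    @property
    def final_val_loss(self) -> float:
        return self.val_loss[-1] if self.val_loss else float("nan")


def _stack_dataset(
    dataset: list[tuple[WindowedTrace | np.ndarray, LabelVector]], dtype
) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for trace, labels in dataset:
        x = normalize_trace(trace) if isinstance(trace, WindowedTrace) else np.asarray(trace)
        if x.shape != (WINDOW_LEN,):
            raise ValueError(f"expected {WINDOW_LEN}-sample inputs, got {x.shape}")
        xs.append(x)
        ys.append(labels.targets if isinstance(labels, LabelVector) else np.asarray(labels))
    X = np.stack(xs, axis=1)[:, :, None].astype(dtype)  # (T, N, 1)
    Y = np.stack(ys, axis=1).astype(np.int64)  # (T, N)
    return X, Y


def train(
    model: SequenceModel,
    dataset: list[tuple[WindowedTrace | np.ndarray, LabelVector]],
    config: SequenceModelConfig | None = None,
) -> tuple[SequenceModel, TrainingLog]:
    """Optimize the model on (normalized trace, augmented labels) pairs.

    A validation subset (``val_fraction`` of the provided data, carved off
    deterministically from the training material, never a held-out test
    set) is scored once per epoch with frozen weights.
    """
    config = config or model.config
    if not dataset:
        raise ValueError("dataset must be nonempty")
    dtype = np.dtype(config.dtype)
    X, Y = _stack_dataset(dataset, dtype)
    n = X.shape[1]
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n_val = int(round(config.val_fraction * n)) if n > 1 else 0
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    Xtr, Ytr = X[:, train_idx], Y[:, train_idx]
    Xva, Yva = X[:, val_idx], Y[:, val_idx]

    opt = _Adam(model.parameters(), config.learning_rate)
    log = TrainingLog(config=config)
    n_tr = Xtr.shape[1]
    for _epoch in range(config.epochs):
        order = rng.permutation(n_tr)
        losses = []
        for start in range(0, n_tr, config.batch_size):
            sel = order[start : start + config.batch_size]
            loss = sequence_loss_and_grad(model, Xtr[:, sel], Ytr[:, sel])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {_epoch}; "
                    "reduce the learning rate or check the inputs"
                )
            opt.step(model.parameters(), model.gradients())
            losses.append(loss * len(sel))
        log.train_loss.append(float(np.sum(losses) / n_tr))
        if n_val:
            log.val_loss.append(
                sequence_loss_and_grad(model, Xva, Yva, compute_grad=False)
            )
    return model, log


def predict_probs(model: SequenceModel, trace: WindowedTrace | np.ndarray) -> np.ndarray:
    """Per-step probability of the feature class for one window.

    ``WindowedTrace`` inputs are z-scored with the same normalization used
    in training; bare arrays are taken as already normalized.
    """
    x = normalize_trace(trace) if isinstance(trace, WindowedTrace) else np.asarray(trace)
    if x.shape != (WINDOW_LEN,):
        raise ValueError(f"expected {WINDOW_LEN} samples, got {x.shape}")
    X = x[:, None, None].astype(np.dtype(model.config.dtype))
    return softmax(model.logits(X))[:, 0, 1].astype(float)


def predict_probs_batch(
    model: SequenceModel, traces: list[WindowedTrace | np.ndarray], batch_size: int = 128
) -> np.ndarray:
    """Vectorized prediction; returns (n_traces, 321) probabilities."""
    xs = [
        normalize_trace(t) if isinstance(t, WindowedTrace) else np.asarray(t)
        for t in traces
    ]
    dtype = np.dtype(model.config.dtype)
    out = np.empty((len(xs), WINDOW_LEN))
    for start in range(0, len(xs), batch_size):
        X = np.stack(xs[start : start + batch_size], axis=1)[:, :, None].astype(dtype)
        out[start : start + X.shape[1]] = softmax(model.logits(X))[:, :, 1].T
    return out


def save_model(model: SequenceModel, path: str | Path) -> None:
    """Write parameters as ``.npz`` with a JSON config sidecar."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.parameters())
    path.with_suffix(".json").write_text(
        json.dumps(asdict(model.config), indent=1), encoding="utf-8"
    )


def load_model(path: str | Path) -> SequenceModel:
    path = Path(path)
    config = SequenceModelConfig(
        **json.loads(path.with_suffix(".json").read_text(encoding="utf-8"))
    )
    model = build_model(config)
    with np.load(path.with_suffix(".npz")) as data:
        params = model.parameters()
        for k, v in params.items():
            v[...] = data[k]
    return model
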