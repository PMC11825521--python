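"""Recurrent five-state classifier, implemented directly in numpy.

The network is a stack of three LSTM layers (the first two return
sequences and are each followed by batch normalization), two ReLU dense
layers, and a softmax output. Gate arithmetic per cell and time step:

    f_t = σ(W_f · [h_{t−1}, x_t] + b_f)        forget gate
    i_t = σ(W_i · [h_{t−1}, x_t] + b_i)        input gate
    C̃_t = tanh(W_C · [h_{t−1}, x_t] + b_C)     candidate cell state
    C_t = f_t ⊙ C_{t−1} + i_t ⊙ C̃_t           cell state
    o_t = σ(W_o · [h_{t−1}, x_t] + b_o)        output gate
    h_t = o_t ⊙ tanh(C_t)                      hidden state

Training minimizes categorical cross-entropy (plus an L2 penalty on the
LSTM weight matrices) with Adam, early stopping on a stratified
validation split, and best-weight restoration. Every epoch is presented
as a length-1 sequence of its projected feature vector by default;
longer windows are supported by passing 3-D input.

Everything is plain float64 numpy, so a fixed seed gives bit-identical
training runs and no state survives between folds.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "LSTMConfig",
    "CellState",
    "LSTMModel",
    "lstm_cell_step",
    "build_model",
    "train",
    "predict",
]

logger = logging.getLogger(__name__)

GATES = ("f", "i", "C", "o")


@dataclass(frozen=True)
class LSTMConfig:
    """Architecture and training hyper-parameters.

    The full-size defaults (500/250/100 units, dense 100/50, L2 1e-4,
    batch 128, learning rate 1e-4, 50 epochs, patience 10) describe the
    network as designed for a ~17k-epoch clinical training set.
    :meth:`reduced` gives a desk-scale preset for small synthetic
    cohorts: smaller layers and an optimizer scaled to few hundred rows.
    """

    layer_units: tuple[int, ...] = (500, 250, 100)
    dense_units: tuple[int, ...] = (100, 50)
    n_classes: int = 5
    l2_factor: float = 1e-4
    learning_rate: float = 1e-4
    batch_size: int = 128
    max_epochs: int = 50
    patience: int = 10
    validation_fraction: float = 0.1
    seed: int = 0
    reduced_mode: bool = False

    def __post_init__(self):
        if any(u < 1 for u in self.layer_units + self.dense_units):
            raise ValueError("all unit counts must be >= 1")
        if not 0 < self.validation_fraction < 0.5:
            raise ValueError("validation_fraction must lie in (0, 0.5)")

    @classmethod
    def reduced(cls, seed: int = 0, **overrides) -> "LSTMConfig":
        """Desk-scale preset: layers [64, 32, 16], dense [32, 16],
        learning rate 3e-3, batch 64, up to 60 epochs."""
        defaults = dict(
            layer_units=(64, 32, 16),
            dense_units=(32, 16),
            learning_rate=3e-3,
            batch_size=64,
            max_epochs=60,
            patience=10,
            seed=seed,
            reduced_mode=True,
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class CellState:
    """State of one LSTM cell after a step."""

    h: np.ndarray
    C: np.ndarray
    f: np.ndarray = None
    i: np.ndarray = None
    o: np.ndarray = None
    candidate: np.ndarray = None


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def lstm_cell_step(x_t: np.ndarray, prev: CellState, params: dict[str, np.ndarray]) -> CellState:
    """One cell update from the gate equations.

    ``params`` holds ``W_f/W_i/W_C/W_o`` of shape (units, units + input
    dim), acting on the concatenation [h_prev, x_t], and biases
    ``b_f/b_i/b_C/b_o``.
    """
    z = np.concatenate([prev.h, x_t])
    units = prev.h.shape[0]
    if params["W_f"].shape != (units, z.shape[0]):
        raise ValueError(
            f"W_f shape {params['W_f'].shape} inconsistent with "
            f"[h, x] of length {z.shape[0]}"
        )
    f = _sigmoid(params["W_f"] @ z + params["b_f"])
    i = _sigmoid(params["W_i"] @ z + params["b_i"])
    g = np.tanh(params["W_C"] @ z + params["b_C"])
    o = _sigmoid(params["W_o"] @ z + params["b_o"])
    C = f * prev.C + i * g
    h = o * np.tanh(C)
    return CellState(h=h, C=C, f=f, i=i, o=o, candidate=g)


# ---------------------------------------------------------------------------
# layers (batched)
# ---------------------------------------------------------------------------


def _init_lstm_layer(rng: np.random.Generator, input_dim: int, units: int) -> dict:
    fan = input_dim + units
    limit = np.sqrt(6.0 / (fan + units))
    params = {}
    for gate in GATES:
        params[f"W_{gate}"] = rng.uniform(-limit, limit, size=(units, fan))
        params[f"b_{gate}"] = np.zeros(units)
    params["b_f"] = np.ones(units)  # standard forget-bias init
    return params


def _lstm_forward(X: np.ndarray, params: dict, return_sequences: bool):
    """X: (B, T, D) -> outputs and the cache needed for BPTT."""
    B, T, D = X.shape
    H = params["b_f"].shape[0]
    h = np.zeros((B, H))
    C = np.zeros((B, H))
    steps = []
    hs = np.empty((B, T, H))
    for t in range(T):
        z = np.concatenate([h, X[:, t, :]], axis=1)  # (B, H + D)
        f = _sigmoid(z @ params["W_f"].T + params["b_f"])
        i = _sigmoid(z @ params["W_i"].T + params["b_i"])
        g = np.tanh(z @ params["W_C"].T + params["b_C"])
        o = _sigmoid(z @ params["W_o"].T + params["b_o"])
        C_prev = C
        C = f * C_prev + i * g
        tanhC = np.tanh(C)
        h = o * tanhC
        hs[:, t, :] = h
        steps.append((z, f, i, g, o, C_prev, tanhC))
    cache = (steps, X.shape, H)
    return (hs if return_sequences else h), cache


def _lstm_backward(dH, cache, params):
    """dH: (B, T, H) for sequence output or (B, H) for last-step output."""
    steps, (B, T, D), H = cache
    grads = {k: np.zeros_like(v) for k, v in params.items()}
    dX = np.zeros((B, T, D))
    dh_next = np.zeros((B, H))
    dC_next = np.zeros((B, H))
    seq = dH.ndim == 3
    for t in reversed(range(T)):
        z, f, i, g, o, C_prev, tanhC = steps[t]
        dh = dh_next + (dH[:, t, :] if seq else (dH if t == T - 1 else 0.0))
        do = dh * tanhC
        dC = dC_next + dh * o * (1.0 - tanhC**2)
        df = dC * C_prev
        di = dC * g
        dg = dC * i
        da_f = df * f * (1.0 - f)
        da_i = di * i * (1.0 - i)
        da_g = dg * (1.0 - g**2)
        da_o = do * o * (1.0 - o)
        for gate, da in zip(GATES, (da_f, da_i, da_g, da_o)):
            grads[f"W_{gate}"] += da.T @ z
            grads[f"b_{gate}"] += da.sum(axis=0)
        dz = da_f @ params["W_f"] + da_i @ params["W_i"] + da_g @ params["W_C"] + da_o @ params["W_o"]
        dh_next = dz[:, :H]
        dX[:, t, :] = dz[:, H:]
        dC_next = dC * f
    return dX, grads


def _init_bn(units: int) -> dict:
    return {
        "gamma": np.ones(units),
        "beta": np.zeros(units),
        "running_mean": np.zeros(units),
        "running_var": np.ones(units),
    }


_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9


def _bn_forward(X, bn, training: bool):
    """Batch normalization over all leading axes, per feature."""
    shape = X.shape
    flat = X.reshape(-1, shape[-1])
    if training:
        mean = flat.mean(axis=0)
        var = flat.var(axis=0)
        bn["running_mean"] = _BN_MOMENTUM * bn["running_mean"] + (1 - _BN_MOMENTUM) * mean
        bn["running_var"] = _BN_MOMENTUM * bn["running_var"] + (1 - _BN_MOMENTUM) * var
    else:
        mean = bn["running_mean"]
        var = bn["running_var"]
    std = np.sqrt(var + _BN_EPS)
    xhat = (flat - mean) / std
    out = bn["gamma"] * xhat + bn["beta"]
    return out.reshape(shape), (xhat, std, shape)


def _bn_backward(dY, cache, bn):
    xhat, std, shape = cache
    dflat = dY.reshape(-1, shape[-1])
    n = dflat.shape[0]
    dgamma = (dflat * xhat).sum(axis=0)
    dbeta = dflat.sum(axis=0)
    dxhat = dflat * bn["gamma"]
    dx = (dxhat - dxhat.mean(axis=0) - xhat * (dxhat * xhat).mean(axis=0)) / std
    return dx.reshape(shape), {"gamma": dgamma, "beta": dbeta}


def _init_dense(rng, input_dim, units) -> dict:
    limit = np.sqrt(6.0 / (input_dim + units))
    return {"W": rng.uniform(-limit, limit, size=(units, input_dim)), "b": np.zeros(units)}


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


@dataclass
class LSTMModel:
    """Parameter container for the stacked network."""

    config: LSTMConfig
    input_dim: int
    lstm_layers: list = field(default_factory=list)
    bn_layers: list = field(default_factory=list)
    dense_layers: list = field(default_factory=list)
    output_layer: dict = field(default_factory=dict)
    classes_: np.ndarray | None = None

    @property
    def parameter_count(self) -> int:
        """Trainable parameters (batch-norm running stats excluded)."""
        n = 0
        for layer in self.lstm_layers:
            n += sum(p.size for p in layer.values())
        for bn in self.bn_layers:
            n += bn["gamma"].size + bn["beta"].size
        for layer in self.dense_layers + [self.output_layer]:
            n += layer["W"].size + layer["b"].size
        return n

    def _trainable(self):
        """(container, key) pairs for every trainable array."""
        out = []
        for layer in self.lstm_layers:
            out += [(layer, k) for k in sorted(layer)]
        for bn in self.bn_layers:
            out += [(bn, "gamma"), (bn, "beta")]
        for layer in self.dense_layers + [self.output_layer]:
            out += [(layer, "W"), (layer, "b")]
        return out

    def snapshot(self) -> dict:
        return {
            "lstm": copy.deepcopy(self.lstm_layers),
            "bn": copy.deepcopy(self.bn_layers),
            "dense": copy.deepcopy(self.dense_layers),
            "out": copy.deepcopy(self.output_layer),
        }

    def restore(self, snap: dict) -> None:
        self.lstm_layers = copy.deepcopy(snap["lstm"])
        self.bn_layers = copy.deepcopy(snap["bn"])
        self.dense_layers = copy.deepcopy(snap["dense"])
        self.output_layer = copy.deepcopy(snap["out"])

    def save(self, out_dir: str | Path) -> None:
        """Text checkpoint: parameters + config echo."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        blob = {
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in self.config.__dict__.items()},
            "input_dim": self.input_dim,
            "classes": None if self.classes_ is None else self.classes_.tolist(),
            "lstm_layers": [{k: v.tolist() for k, v in l.items()} for l in self.lstm_layers],
            "bn_layers": [{k: v.tolist() for k, v in l.items()} for l in self.bn_layers],
            "dense_layers": [{k: v.tolist() for k, v in l.items()} for l in self.dense_layers],
            "output_layer": {k: v.tolist() for k, v in self.output_layer.items()},
        }
        (out / "model.json").write_text(json.dumps(blob))

    @classmethod
    def load(cls, in_dir: str | Path) -> "LSTMModel":
        blob = json.loads((Path(in_dir) / "model.json").read_text())
        cfg = blob["config"]
        cfg["layer_units"] = tuple(cfg["layer_units"])
        cfg["dense_units"] = tuple(cfg["dense_units"])
        model = cls(config=LSTMConfig(**cfg), input_dim=blob["input_dim"])
        model.lstm_layers = [{k: np.array(v) for k, v in l.items()} for l in blob["lstm_layers"]]
        model.bn_layers = [{k: np.array(v) for k, v in l.items()} for l in blob["bn_layers"]]
        model.dense_layers = [{k: np.array(v) for k, v in l.items()} for l in blob["dense_layers"]]
        model.output_layer = {k: np.array(v) for k, v in blob["output_layer"].items()}
        if blob["classes"] is not None:
            model.classes_ = np.array(blob["classes"])
        return model


def build_model(config: LSTMConfig, input_dim: int) -> LSTMModel:
    """Assemble the stack with seeded Glorot initialization."""
    if input_dim < 1:
        raise ValueError("input_dim must be >= 1")
    rng = np.random.default_rng(config.seed)
    model = LSTMModel(config=config, input_dim=input_dim)
    d = input_dim
    for j, units in enumerate(config.layer_units):
        model.lstm_layers.append(_init_lstm_layer(rng, d, units))
        if j < len(config.layer_units) - 1:
            model.bn_layers.append(_init_bn(units))
        d = units
    for units in config.dense_units:
        model.dense_layers.append(_init_dense(rng, d, units))
        d = units
    model.output_layer = _init_dense(rng, d, config.n_classes)
    return model


def _forward(model: LSTMModel, X: np.ndarray, training: bool):
    """X: (B, T, D) -> class probabilities (B, n_classes) + caches."""
    caches = []
    out = X
    n_lstm = len(model.lstm_layers)
    for j, layer in enumerate(model.lstm_layers):
        return_seq = j < n_lstm - 1
        out, cache = _lstm_forward(out, layer, return_sequences=return_seq)
        caches.append(("lstm", cache))
        if return_seq:
            out, bn_cache = _bn_forward(out, model.bn_layers[j], training)
            caches.append(("bn", bn_cache))
    for layer in model.dense_layers:
        a = out @ layer["W"].T + layer["b"]
        out_relu = np.maximum(a, 0.0)
        caches.append(("dense", (out, a)))
        out = out_relu
    logits = out @ model.output_layer["W"].T + model.output_layer["b"]
    caches.append(("out", out))
    logits -= logits.max(axis=1, keepdims=True)
    exp = np.exp(logits)
    probs = exp / exp.sum(axis=1, keepdims=True)
    return probs, caches


def _l2_penalty(model: LSTMModel) -> float:
    return model.config.l2_factor * sum(
        float(np.sum(layer[f"W_{g}"] ** 2))
        for layer in model.lstm_layers
        for g in GATES
    )


def _backward(model: LSTMModel, probs, caches, Y_onehot):
    """Gradients of mean cross-entropy + L2 wrt every trainable array,
    keyed like :meth:`LSTMModel._trainable`."""
    B = probs.shape[0]
    grads: dict[int, dict] = {}
    dlogits = (probs - Y_onehot) / B
    kind, pre_out = caches[-1]
    grads_out = {"W": dlogits.T @ pre_out, "b": dlogits.sum(axis=0)}
    d = dlogits @ model.output_layer["W"]
    dense_grads = []
    ci = len(caches) - 2
    for layer in reversed(model.dense_layers):
        kind, (inp, a) = caches[ci]
        d = d * (a > 0)
        dense_grads.append({"W": d.T @ inp, "b": d.sum(axis=0)})
        d = d @ layer["W"]
        ci -= 1
    dense_grads.reverse()
    lstm_grads = [None] * len(model.lstm_layers)
    bn_grads = [None] * len(model.bn_layers)
    for j in reversed(range(len(model.lstm_layers))):
        if j < len(model.lstm_layers) - 1:
            kind, bn_cache = caches[ci]
            d, bn_g = _bn_backward(d, bn_cache, model.bn_layers[j])
            bn_grads[j] = bn_g
            ci -= 1
        kind, cache = caches[ci]
        d, layer_g = _lstm_backward(d, cache, model.lstm_layers[j])
        # L2 on the LSTM weight matrices
        for g in GATES:
            layer_g[f"W_{g}"] += 2.0 * model.config.l2_factor * model.lstm_layers[j][f"W_{g}"]
        lstm_grads[j] = layer_g
        ci -= 1
    flat = []
    for layer_g in lstm_grads:
        flat += [layer_g[k] for k in sorted(layer_g)]
    for bn_g in bn_grads:
        flat += [bn_g["gamma"], bn_g["beta"]]
    for g in dense_grads:
        flat += [g["W"], g["b"]]
    flat += [grads_out["W"], grads_out["b"]]
    return flat


def _as_3d(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        X = X[:, None, :]  # each row is a length-1 sequence
    if X.ndim != 3:
        raise ValueError("X must be (n, features) or (n, timesteps, features)")
    return X


def _loss_and_acc(model, X, Y_onehot, y_idx):
    probs, _ = _forward(model, X, training=False)
    ce = -np.mean(np.log(np.maximum(probs[np.arange(len(y_idx)), y_idx], 1e-300)))
    acc = float(np.mean(probs.argmax(axis=1) == y_idx))
    return float(ce + _l2_penalty(model)), acc


def train(
    model: LSTMModel,
    X: np.ndarray,
    y: np.ndarray,
    config: LSTMConfig | None = None,
) -> dict:
    """Fit the model; returns the per-epoch history.

    Cross-entropy + L2 minimized with Adam; ``validation_fraction`` of
    the rows (stratified) monitors early stopping on validation loss,
    with best-weight restoration. History lists have one entry per epoch
    actually run.
    """
    from sklearn.model_selection import train_test_split

    config = config or model.config
    X = _as_3d(X)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training requires at least 2 classes")
    model.classes_ = classes
    class_index = {c: k for k, c in enumerate(classes)}
    y_idx = np.array([class_index[c] for c in y])

    idx_train, idx_val = train_test_split(
        np.arange(len(y_idx)),
        test_size=config.validation_fraction,
        stratify=y_idx,
        random_state=config.seed,
    )
    Xt, yt = X[idx_train], y_idx[idx_train]
    Xv, yv = X[idx_val], y_idx[idx_val]
    n_out = model.output_layer["b"].shape[0]
    Yt = np.eye(n_out)[yt]
    Yv = np.eye(n_out)[yv]

    slots = model._trainable()
    m = [np.zeros_like(c[k]) for c, k in slots]
    v = [np.zeros_like(c[k]) for c, k in slots]
    b1, b2, eps = 0.9, 0.999, 1e-8
    step = 0
    rng = np.random.default_rng(config.seed)

    history = {"loss": [], "accuracy": [], "val_loss": [], "val_accuracy": []}
    best_val = np.inf
    best_snap = model.snapshot()
    best_epoch = 0
    since_improve = 0

    for epoch in range(config.max_epochs):
        order = rng.permutation(len(yt))
        for start in range(0, len(yt), config.batch_size):
            sel = order[start : start + config.batch_size]
            probs, caches = _forward(model, Xt[sel], training=True)
            grads = _backward(model, probs, caches, Yt[sel])
            step += 1
            lr_t = config.learning_rate * np.sqrt(1 - b2**step) / (1 - b1**step)
            for slot, grad, mi, vi in zip(slots, grads, m, v):
                container, key = slot
                mi *= b1
                mi += (1 - b1) * grad
                vi *= b2
                vi += (1 - b2) * grad**2
                container[key] = container[key] - lr_t * mi / (np.sqrt(vi) + eps)

        tr_loss, tr_acc = _loss_and_acc(model, Xt, Yt, yt)
        va_loss, va_acc = _loss_and_acc(model, Xv, Yv, yv)
        history["loss"].append(tr_loss)
        history["accuracy"].append(tr_acc)
        history["val_loss"].append(va_loss)
        history["val_accuracy"].append(va_acc)
        if va_loss < best_val - 1e-12:
            best_val = va_loss
            best_snap = model.snapshot()
            best_epoch = epoch
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= config.patience:
                logger.info("early stop at epoch %d (best %d)", epoch + 1, best_epoch + 1)
                break

    model.restore(best_snap)
    history["stopped_epoch"] = len(history["loss"])
    history["best_epoch"] = best_epoch + 1
    return history


def predict(model: LSTMModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities and argmax labels (ties -> lowest class code)."""
    X = _as_3d(X)
    if X.shape[2] != model.input_dim:
        raise ValueError(
            f"feature dimension {X.shape[2]} != model input dim {model.input_dim}"
        )
    probs, _ = _forward(model, X, training=False)
    if model.classes_ is None:
        labels = probs.argmax(axis=1)
    else:
        labels = model.classes_[probs.argmax(axis=1)]
    return probs, labels
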