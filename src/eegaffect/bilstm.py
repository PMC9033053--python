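"""Stacked bidirectional LSTM binary classifier, implemented from scratch.

Each LSTM cell follows the standard gate equations

    f_t = sigmoid(W_f [h_{t-1}, x_t] + b_f)        (forget gate)
    i_t = sigmoid(W_i [h_{t-1}, x_t] + b_i)        (input gate)
    c~_t = tanh(W_c [h_{t-1}, x_t] + b_c)          (candidate state)
    C_t = f_t * C_{t-1} + i_t * c~_t               (cell state)
    o_t = sigmoid(W_o [h_{t-1}, x_t] + b_o)        (output gate)
    h_t = o_t * tanh(C_t)

A bidirectional layer runs one pass forward in time and one backward; a
per-step combination map O_t = tanh(W4 h_fwd_t + W6 h_back_t) feeds stacked
layers, and the sequence-level decision concatenates the last forward state
with the first backward state of the top layer into a 2-class softmax.

Training is minibatch Adam with global-norm gradient clipping, the data
shuffled once before training; gradients are exact BPTT (verified against
central finite differences in the test suite).  Feature vectors are encoded
as length-d sequences of scalars in fixed column order by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .features import FeatureMatrix
from .io_deap import BinaryLabelSet

GATES = ("f", "i", "c", "o")


class NumericalError(FloatingPointError):
    """A non-finite value appeared in a named gate computation."""


@dataclass
class TrainConfig:
    """Training recipe; defaults follow the published settings table."""

    learning_rate: float = 0.01
    max_epochs: int = 35
    minibatch_size: int = 80
    hidden_units: int = 100
    gradient_clip_threshold: float = 1.0  # global L2 norm
    n_layers: int = 2  # stacked bidirectional layers
    encoding: str = "sequence"  # "sequence": d scalar steps; "vector": one step
    standardize: bool = True
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    dtype: str = "float32"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("max_epochs", "minibatch_size", "hidden_units",
                     "gradient_clip_threshold", "n_layers"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")


class DirectionParams:
    """Gate weights for one direction: W_* act on [h_{t-1}, x_t]."""

    def __init__(self, input_dim: int, hidden: int, rng: np.random.Generator,
                 dtype=np.float64) -> None:
        self.input_dim = input_dim
        self.hidden = hidden
        bound = 1.0 / np.sqrt(max(input_dim, 1))
        for g in GATES:
            # recurrent block orthogonal, input block uniform fan-in
            q, _ = np.linalg.qr(rng.standard_normal((hidden, hidden)))
            wx = rng.uniform(-bound, bound, size=(input_dim, hidden))
            setattr(self, f"W{g}", np.vstack([q, wx]).astype(dtype))
            b = np.zeros(hidden, dtype=dtype)
            if g == "f":
                b += 1.0  # forget-gate bias +1: remember by default
            setattr(self, f"b{g}", b)

    def param_items(self, prefix: str):
        for g in GATES:
            yield f"{prefix}W{g}", getattr(self, f"W{g}")
            yield f"{prefix}b{g}", getattr(self, f"b{g}")


class BiLSTMParams:
    """All parameters of the stacked bidirectional classifier."""

    def __init__(self, input_dim: int, hidden: int, n_layers: int,
                 seed: int = 0, dtype=np.float64) -> None:
        rng = np.random.default_rng(seed)
        self.hidden = hidden
        self.n_layers = n_layers
        self.input_dim = input_dim
        self.layers = []
        d_in = input_dim
        bound_h = 1.0 / np.sqrt(hidden)
        for li in range(n_layers):
            fwd = DirectionParams(d_in, hidden, rng, dtype)
            bwd = DirectionParams(d_in, hidden, rng, dtype)
            layer = {"fwd": fwd, "bwd": bwd}
            if li < n_layers - 1:
                # per-step combination O_t = tanh(Wcf h_fwd + Wcb h_back)
                layer["Wcf"] = rng.uniform(-bound_h, bound_h, (hidden, hidden)).astype(dtype)
                layer["Wcb"] = rng.uniform(-bound_h, bound_h, (hidden, hidden)).astype(dtype)
            self.layers.append(layer)
            d_in = hidden
        bound_d = 1.0 / np.sqrt(2 * hidden)
        self.Wdense = rng.uniform(-bound_d, bound_d, (2 * hidden, 2)).astype(dtype)
        self.bdense = np.zeros(2, dtype=dtype)

    def param_items(self):
        for li, layer in enumerate(self.layers):
            yield from layer["fwd"].param_items(f"l{li}_fwd_")
            yield from layer["bwd"].param_items(f"l{li}_bwd_")
            if "Wcf" in layer:
                yield f"l{li}_Wcf", layer["Wcf"]
                yield f"l{li}_Wcb", layer["Wcb"]
        yield "Wdense", self.Wdense
        yield "bdense", self.bdense

    def get(self, name: str) -> np.ndarray:
        for k, v in self.param_items():
            if k == name:
                return v
        raise KeyError(name)

    def set_(self, name: str, value: np.ndarray) -> None:
        if name == "Wdense":
            self.Wdense = value
            return
        if name == "bdense":
            self.bdense = value
            return
        li = int(name[1:name.index("_")])
        rest = name[name.index("_") + 1:]
        layer = self.layers[li]
        if rest in ("Wcf", "Wcb"):
            layer[rest] = value
            return
        direction, pname = rest.split("_")
        setattr(layer[direction], pname, value)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def lstm_cell_step(x_t: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray,
                   params: DirectionParams) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM cell update; accepts vectors or (batch, dim) arrays."""
    x_t = np.atleast_2d(np.asarray(x_t, dtype=float))
    h_prev = np.atleast_2d(np.asarray(h_prev, dtype=float))
    c_prev = np.atleast_2d(np.asarray(c_prev, dtype=float))
    z = np.concatenate([h_prev, x_t], axis=1)
    acts = {}
    for g in GATES:
        with np.errstate(invalid="ignore"):
            a = z @ getattr(params, f"W{g}") + getattr(params, f"b{g}")
        if not np.all(np.isfinite(a)):
            raise NumericalError(f"non-finite value in gate '{g}'")
        acts[g] = np.tanh(a) if g == "c" else _sigmoid(a)
    c_t = acts["f"] * c_prev + acts["i"] * acts["c"]
    h_t = acts["o"] * np.tanh(c_t)
    return np.squeeze(h_t), np.squeeze(c_t)


# ---------------------------------------------------------------------------
# batched forward / backward


def _direction_forward(X: np.ndarray, p: DirectionParams, reverse: bool) -> dict:
    """Run one direction over a (B, T, d) batch; cache everything for BPTT."""
    B, T, _ = X.shape
    H = p.hidden
    dtype = X.dtype
    W = np.concatenate([getattr(p, f"W{g}") for g in GATES], axis=1)  # (H+d, 4H)
    b = np.concatenate([getattr(p, f"b{g}") for g in GATES])
    Wh, Wx = W[:H], W[H:]
    xproj = X @ Wx + b  # (B, T, 4H)
    order = range(T - 1, -1, -1) if reverse else range(T)
    h = np.zeros((B, H), dtype=dtype)
    c = np.zeros((B, H), dtype=dtype)
    cache = {
        "h": np.empty((B, T, H), dtype=dtype), "c": np.empty((B, T, H), dtype=dtype),
        "f": np.empty((B, T, H), dtype=dtype), "i": np.empty((B, T, H), dtype=dtype),
        "g": np.empty((B, T, H), dtype=dtype), "o": np.empty((B, T, H), dtype=dtype),
        "tc": np.empty((B, T, H), dtype=dtype), "hprev": np.empty((B, T, H), dtype=dtype),
    }
    for t in order:
        a = h @ Wh + xproj[:, t]
        f = _sigmoid(a[:, :H])
        i = _sigmoid(a[:, H:2 * H])
        g = np.tanh(a[:, 2 * H:3 * H])
        o = _sigmoid(a[:, 3 * H:])
        cache["hprev"][:, t] = h
        cprev = c
        c = f * cprev + i * g
        tc = np.tanh(c)
        h = o * tc
        for k, v in (("h", h), ("c", c), ("f", f), ("i", i), ("g", g), ("o", o), ("tc", tc)):
            cache[k][:, t] = v
    cache["reverse"] = reverse
    return cache


def _direction_backward(X: np.ndarray, p: DirectionParams, cache: dict,
                        dH: np.ndarray) -> tuple[np.ndarray, dict]:
    """BPTT for one direction given dLoss/d(h at every step).  Returns dX."""
    B, T, d = X.shape
    H = p.hidden
    W = np.concatenate([getattr(p, f"W{g}") for g in GATES], axis=1)
    Wh, Wx = W[:H], W[H:]
    dW = np.zeros_like(W)
    db = np.zeros(4 * H, dtype=W.dtype)
    dX = np.zeros_like(X)
    dh_next = np.zeros((B, H), dtype=X.dtype)
    dc_next = np.zeros((B, H), dtype=X.dtype)
    order = range(T) if cache["reverse"] else range(T - 1, -1, -1)
    for t in order:
        f, i, g, o = cache["f"][:, t], cache["i"][:, t], cache["g"][:, t], cache["o"][:, t]
        tc = cache["tc"][:, t]
        if cache["reverse"]:
            cprev = cache["c"][:, t + 1] if t + 1 < T else np.zeros((B, H), dtype=X.dtype)
        else:
            cprev = cache["c"][:, t - 1] if t > 0 else np.zeros((B, H), dtype=X.dtype)
        dh = dH[:, t] + dh_next
        do = dh * tc
        dc = dc_next + dh * o * (1.0 - tc**2)
        df = dc * cprev
        di = dc * g
        dg = dc * i
        dc_next = dc * f
        da = np.concatenate(
            [df * f * (1 - f), di * i * (1 - i), dg * (1 - g**2), do * o * (1 - o)], axis=1
        )
        z = np.concatenate([cache["hprev"][:, t], X[:, t]], axis=1)
        dW += z.T @ da
        db += da.sum(axis=0)
        dz = da @ W.T
        dh_next = dz[:, :H]
        dX[:, t] = dz[:, H:]
    grads = {}
    for gi, g in enumerate(GATES):
        grads[f"W{g}"] = dW[:, gi * H:(gi + 1) * H]
        grads[f"b{g}"] = db[gi * H:(gi + 1) * H]
    return dX, grads


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def bilstm_forward(X: np.ndarray, params: BiLSTMParams,
                   return_cache: bool = False):
    """Class scores (softmax over 2) for a (B, T, d) batch."""
    X = np.asarray(X)
    if X.ndim == 2:
        X = X[None]
    if X.shape[1] == 0:
        raise ValueError("empty sequence")
    caches = []
    inp = X
    for li, layer in enumerate(params.layers):
        cf = _direction_forward(inp, layer["fwd"], reverse=False)
        cb = _direction_forward(inp, layer["bwd"], reverse=True)
        rec = {"cf": cf, "cb": cb, "inp": inp}
        if li < params.n_layers - 1:
            A = cf["h"] @ layer["Wcf"] + cb["h"] @ layer["Wcb"]
            O = np.tanh(A)
            rec["O"] = O
            inp = O
        caches.append(rec)
    top_f = caches[-1]["cf"]["h"][:, -1]   # last forward state
    top_b = caches[-1]["cb"]["h"][:, 0]    # first backward state
    feat = np.concatenate([top_f, top_b], axis=1)
    logits = feat @ params.Wdense + params.bdense
    scores = _softmax(logits)
    if return_cache:
        return scores, {"layers": caches, "feat": feat}
    return scores


def loss_and_grads(X: np.ndarray, y: np.ndarray, params: BiLSTMParams
                   ) -> tuple[float, dict[str, np.ndarray]]:
    """Mean cross-entropy and exact gradients for a batch."""
    y = np.asarray(y, dtype=int)
    scores, cache = bilstm_forward(X, params, return_cache=True)
    B, T = X.shape[0], X.shape[1]
    eps = 1e-12
    loss = float(-np.mean(np.log(scores[np.arange(B), y] + eps)))
    dlogits = scores.copy()
    dlogits[np.arange(B), y] -= 1.0
    dlogits /= B
    grads: dict[str, np.ndarray] = {
        "Wdense": cache["feat"].T @ dlogits,
        "bdense": dlogits.sum(axis=0),
    }
    dfeat = dlogits @ params.Wdense.T
    H = params.hidden
    d_next_inp = None
    for li in range(params.n_layers - 1, -1, -1):
        layer = params.layers[li]
        rec = cache["layers"][li]
        dHf = np.zeros_like(rec["cf"]["h"])
        dHb = np.zeros_like(rec["cb"]["h"])
        if li == params.n_layers - 1:
            dHf[:, -1] += dfeat[:, :H]
            dHb[:, 0] += dfeat[:, H:]
        if li < params.n_layers - 1:
            dA = d_next_inp * (1.0 - rec["O"] ** 2)
            grads[f"l{li}_Wcf"] = np.einsum("bth,btk->hk", rec["cf"]["h"], dA)
            grads[f"l{li}_Wcb"] = np.einsum("bth,btk->hk", rec["cb"]["h"], dA)
            dHf += dA @ layer["Wcf"].T
            dHb += dA @ layer["Wcb"].T
        dXf, gf = _direction_backward(rec["inp"], layer["fwd"], rec["cf"], dHf)
        dXb, gb = _direction_backward(rec["inp"], layer["bwd"], rec["cb"], dHb)
        for k, v in gf.items():
            grads[f"l{li}_fwd_{k}"] = v
        for k, v in gb.items():
            grads[f"l{li}_bwd_{k}"] = v
        d_next_inp = dXf + dXb
    return loss, grads


def clip_global_norm(grads: dict[str, np.ndarray], threshold: float) -> float:
    """Scale all gradients so the global L2 norm is at most ``threshold``."""
    total = float(np.sqrt(sum(float(np.sum(g.astype(np.float64) ** 2))
                              for g in grads.values())))
    if total > threshold and total > 0:
        scale = threshold / total
        for k in grads:
            grads[k] = grads[k] * scale
    return total


# ---------------------------------------------------------------------------
# training


@dataclass
class FittedBiLSTM:
    """Fitted model plus everything needed to reproduce its predictions."""

    params: BiLSTMParams
    config: TrainConfig
    column_names: list[str]
    standardize_mean: np.ndarray
    standardize_sd: np.ndarray
    loss_trace: list[float] = field(default_factory=list)
    accuracy_trace: list[float] = field(default_factory=list)
    gradient_norms: list[float] = field(default_factory=list)

    def encode(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=self.params.Wdense.dtype)
        if self.config.standardize:
            X = (X - self.standardize_mean) / self.standardize_sd
        if self.config.encoding == "sequence":
            return X[:, :, None]  # (B, d, 1): one scalar per step
        return X[:, None, :]      # (B, 1, d): one vector step

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        arrays = {k: v for k, v in self.params.param_items()}
        arrays["standardize_mean"] = self.standardize_mean
        arrays["standardize_sd"] = self.standardize_sd
        arrays["loss_trace"] = np.asarray(self.loss_trace)
        arrays["accuracy_trace"] = np.asarray(self.accuracy_trace)
        meta = dict(asdict(self.config))
        meta["column_names"] = list(self.column_names)
        meta["input_dim"] = self.params.input_dim
        import json

        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "FittedBiLSTM":
        import json

        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            column_names = meta.pop("column_names")
            input_dim = meta.pop("input_dim")
            cfg = TrainConfig(**meta)
            params = BiLSTMParams(input_dim, cfg.hidden_units, cfg.n_layers,
                                  seed=cfg.seed, dtype=np.dtype(cfg.dtype))
            for name, _ in list(params.param_items()):
                params.set_(name, data[name])
            model = cls(params, cfg, column_names,
                        data["standardize_mean"], data["standardize_sd"],
                        list(data["loss_trace"]), list(data["accuracy_trace"]))
        return model


def train(
    X: FeatureMatrix | np.ndarray,
    y: BinaryLabelSet | np.ndarray,
    cfg: Optional[TrainConfig] = None,
) -> FittedBiLSTM:
    """Fit the stacked bidirectional LSTM on feature rows.

    Rows are standardized by training-set statistics, encoded as sequences,
    shuffled once, then optimized with minibatch Adam under global-norm
    gradient clipping.  Fully deterministic for a fixed seed.
    """
    cfg = cfg or TrainConfig()
    dtype = np.dtype(cfg.dtype)
    if isinstance(X, FeatureMatrix):
        column_names = list(X.column_names)
        Xv = X.values
    else:
        Xv = np.asarray(X, dtype=float)
        column_names = [f"f{i}" for i in range(Xv.shape[1])]
    yv = (y.labels if isinstance(y, BinaryLabelSet) else np.asarray(y)).astype(int)
    if np.unique(yv).size < 2:
        raise ValueError("training labels contain a single class")
    mu = Xv.mean(axis=0)
    sd = Xv.std(axis=0)
    sd[sd == 0] = 1.0
    if not cfg.standardize:
        mu = np.zeros_like(mu)
        sd = np.ones_like(sd)
    input_dim = 1 if cfg.encoding == "sequence" else Xv.shape[1]
    params = BiLSTMParams(input_dim, cfg.hidden_units, cfg.n_layers,
                          seed=cfg.seed, dtype=dtype)
    model = FittedBiLSTM(params, cfg, column_names, mu.astype(dtype), sd.astype(dtype))
    Xe = model.encode(Xv)
    rng = np.random.default_rng(cfg.seed + 1)
    order = rng.permutation(Xe.shape[0])  # shuffle once, before training
    Xe, ys = Xe[order], yv[order]
    # Adam state
    m = {k: np.zeros_like(v) for k, v in params.param_items()}
    v = {k: np.zeros_like(vv) for k, vv in params.param_items()}
    step = 0
    n = Xe.shape[0]
    for _epoch in range(cfg.max_epochs):
        epoch_loss, epoch_hits = 0.0, 0
        for start in range(0, n, cfg.minibatch_size):
            xb = Xe[start:start + cfg.minibatch_size]
            yb = ys[start:start + cfg.minibatch_size]
            loss, grads = loss_and_grads(xb, yb, params)
            norm = clip_global_norm(grads, cfg.gradient_clip_threshold)
            model.gradient_norms.append(min(norm, cfg.gradient_clip_threshold))
            step += 1
            if cfg.learning_rate > 0:
                b1t = 1.0 - cfg.adam_beta1**step
                b2t = 1.0 - cfg.adam_beta2**step
                for name, p in params.param_items():
                    g = grads[name]
                    m[name] = cfg.adam_beta1 * m[name] + (1 - cfg.adam_beta1) * g
                    v[name] = cfg.adam_beta2 * v[name] + (1 - cfg.adam_beta2) * g**2
                    update = cfg.learning_rate * (m[name] / b1t) / (
                        np.sqrt(v[name] / b2t) + cfg.adam_eps
                    )
                    params.set_(name, (p - update).astype(dtype))
            epoch_loss += loss * xb.shape[0]
            scores = bilstm_forward(xb, params)
            epoch_hits += int(np.sum(scores.argmax(axis=1) == yb))
        model.loss_trace.append(epoch_loss / n)
        model.accuracy_trace.append(epoch_hits / n)
    return model


def predict(model: FittedBiLSTM, X: FeatureMatrix | np.ndarray
            ) -> tuple[np.ndarray, np.ndarray]:
    """Class labels (0 low / 1 high) and class-1 probabilities."""
    if isinstance(X, FeatureMatrix):
        missing = [c for c in model.column_names if c not in X.column_names]
        if missing:
            raise ValueError(f"feature columns missing: {missing}")
        idx = [X.column_names.index(c) for c in model.column_names]
        Xv = X.values[:, idx]
    else:
        Xv = np.asarray(X, dtype=float)
        if Xv.shape[1] != len(model.column_names):
            raise ValueError(
                f"expected {len(model.column_names)} columns, got {Xv.shape[1]}"
            )
    scores = np.empty((Xv.shape[0], 2))
    Xe = model.encode(Xv)
    for start in range(0, Xe.shape[0], 512):
        scores[start:start + 512] = bilstm_forward(Xe[start:start + 512], model.params)
    probs = scores[:, 1]
    return (probs >= 0.5).astype(int), probs
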