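"""Two-branch CNN -> merge -> bidirectional LSTM -> sigmoid classifier.

The network is implemented directly in NumPy (forward pass, backprop,
RMSprop) because no deep-learning framework is assumed.  Architecture per
branch: valid cross-correlation (16 filters of length 10 by default) ->
batch normalization -> ReLU -> max-pooling (window 3, trailing partial
window kept) -> dropout.  The two pooled maps are concatenated
position-wise along the feature axis and fed to a bidirectional LSTM (32
units per direction); the concatenated final hidden states pass through
dropout and a single sigmoid output unit.  Training minimizes binary
cross-entropy with RMSprop, shuffling each epoch and stopping early on the
validation loss.

Parameters live in a flat ``{name: ndarray}`` dict; the packed LSTM
matrices use gate order (input, forget, candidate, output) and convert to
:class:`~rnabind.nn.layers.LstmParams` via :meth:`NetworkState.lstm_params`.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Any

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .layers import LstmParams, _sigmoid


@dataclass
class ModelConfig:
    """Hyperparameters of the classifier.

    Defaults follow the published setup where stated (16 filters of length
    10 per branch, batch size 50, at most 30 epochs, RMSprop at learning
    rate 0.001, early stopping, dropout, batch normalization); layer sizes
    the publication leaves open (pool window, LSTM width, dropout rates)
    are fixed here and overridable.
    """

    n_filters_seq: int = 16
    n_filters_struct: int = 16
    filter_len_seq: int = 10
    filter_len_struct: int = 10
    pool_window: int = 3
    lstm_hidden: int = 32
    dropout_conv: float = 0.25
    dropout_out: float = 0.5
    batch_norm: bool = True
    bn_momentum: float = 0.9
    bn_eps: float = 1e-3
    learning_rate: float = 0.001
    batch_size: int = 50
    max_epochs: int = 30
    patience: int = 5
    rmsprop_rho: float = 0.9
    rmsprop_eps: float = 1e-8
    input_length: int = 101
    readout: str = "final"  # "final" or "sequence"
    use_structure: bool = True
    use_blstm: bool = True
    struct_filler: str = "T"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_filters_seq", "n_filters_struct", "filter_len_seq", "filter_len_struct",
            "pool_window", "lstm_hidden", "batch_size", "max_epochs", "input_length",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.patience < 0:
            raise ValueError("patience must be >= 0")
        if not (0.0 <= self.dropout_conv < 1.0 and 0.0 <= self.dropout_out < 1.0):
            raise ValueError("dropout rates must be in [0, 1)")
        if self.readout not in ("final", "sequence"):
            raise ValueError("readout must be 'final' or 'sequence'")
        if self.use_structure and self.filter_len_seq != self.filter_len_struct:
            # equal filter lengths keep the two pooled maps the same length,
            # which position-wise merging requires
            raise ValueError("filter lengths must match when both branches are used")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ModelConfig":
        return cls(**d)


def _n_pooled(n_conv: int, window: int) -> int:
    return (n_conv + window - 1) // window


@dataclass
class NetworkState:
    """Parameters, batch-norm running statistics and config of one network."""

    params: dict[str, np.ndarray]
    bn_state: dict[str, np.ndarray]
    config: ModelConfig

    def copy(self) -> "NetworkState":
        return NetworkState(
            {k: v.copy() for k, v in self.params.items()},
            {k: v.copy() for k, v in self.bn_state.items()},
            self.config,
        )

    def lstm_params(self, direction: str) -> LstmParams:
        """Unpack one direction ('fwd' or 'bwd') into per-gate matrices."""
        H = self.config.lstm_hidden
        Wx = self.params[f"lstm_{direction}/Wx"]
        Uh = self.params[f"lstm_{direction}/Uh"]
        b = self.params[f"lstm_{direction}/b"]
        sl = {"i": slice(0, H), "f": slice(H, 2 * H), "c": slice(2 * H, 3 * H), "o": slice(3 * H, 4 * H)}
        kw = {}
        for g, s in sl.items():
            kw[f"W_{g}"] = Wx[:, s].T.copy()
            kw[f"U_{g}"] = Uh[:, s].T.copy()
            kw[f"b_{g}"] = b[s].copy()
        return LstmParams(**kw)


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def build_network(cfg: ModelConfig) -> NetworkState:
    """Initialize all parameters from the config seed (Glorot uniform;
    LSTM forget-gate bias starts at 1)."""
    rng = np.random.default_rng(cfg.seed)
    params: dict[str, np.ndarray] = {}
    bn: dict[str, np.ndarray] = {}
    branches = [("seq", cfg.n_filters_seq, cfg.filter_len_seq, 4)]
    if cfg.use_structure:
        branches.append(("str", cfg.n_filters_struct, cfg.filter_len_struct, 6))
    feat = 0
    for name, F, L, D in branches:
        params[f"{name}/W"] = _glorot(rng, (F, L, D), L * D, F)
        params[f"{name}/b"] = np.zeros(F)
        if cfg.batch_norm:
            params[f"{name}/gamma"] = np.ones(F)
            params[f"{name}/beta"] = np.zeros(F)
            bn[f"{name}/mu"] = np.zeros(F)
            bn[f"{name}/var"] = np.ones(F)
        feat += F
    n_conv = cfg.input_length + cfg.filter_len_seq - 1
    n_pool = _n_pooled(n_conv, cfg.pool_window)
    H = cfg.lstm_hidden
    if cfg.use_blstm:
        for direction in ("fwd", "bwd"):
            params[f"lstm_{direction}/Wx"] = _glorot(rng, (feat, 4 * H), feat, H)
            params[f"lstm_{direction}/Uh"] = _glorot(rng, (H, 4 * H), H, H)
            b = np.zeros(4 * H)
            b[H : 2 * H] = 1.0  # forget gate bias
            params[f"lstm_{direction}/b"] = b
        readout_dim = 2 * H if cfg.readout == "final" else n_pool * 2 * H
    else:
        readout_dim = n_pool * feat
    params["out/W"] = _glorot(rng, (readout_dim,), readout_dim, 1)
    params["out/b"] = np.zeros(1)
    return NetworkState(params, bn, cfg)


# ---------------------------------------------------------------------------
# forward / backward

def _im2col(X: np.ndarray, L: int) -> np.ndarray:
    """(B, P, D) -> (B, T, L*D) sliding windows, T = P - L + 1."""
    win = sliding_window_view(X, L, axis=1)  # (B, T, D, L)
    B, T, D, _ = win.shape
    return np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(B, T, L * D)


def _branch_forward(X, state: NetworkState, name: str, train: bool, rng) -> tuple[np.ndarray, dict]:
    cfg = state.config
    p = state.params
    F, L, D = p[f"{name}/W"].shape
    if X.shape[2] != D:
        raise ValueError(f"channel mismatch in branch {name}: {X.shape[2]} != {D}")
    Xc = _im2col(X, L)
    Z = Xc @ p[f"{name}/W"].reshape(F, L * D).T + p[f"{name}/b"]
    cache: dict[str, Any] = {"Xc": Xc}
    if cfg.batch_norm:
        if train:
            mu = Z.mean(axis=(0, 1))
            var = Z.var(axis=(0, 1))
            m = cfg.bn_momentum
            state.bn_state[f"{name}/mu"] = m * state.bn_state[f"{name}/mu"] + (1 - m) * mu
            state.bn_state[f"{name}/var"] = m * state.bn_state[f"{name}/var"] + (1 - m) * var
        else:
            mu = state.bn_state[f"{name}/mu"]
            var = state.bn_state[f"{name}/var"]
        inv_std = 1.0 / np.sqrt(var + cfg.bn_eps)
        xhat = (Z - mu) * inv_std
        Y = p[f"{name}/gamma"] * xhat + p[f"{name}/beta"]
        cache.update(xhat=xhat, inv_std=inv_std, bn_train=train)
    else:
        Y = Z
    A = np.maximum(Y, 0.0)
    cache["relu_mask"] = Y > 0
    # max pooling with remembered argmax positions
    w = cfg.pool_window
    B, T, _ = A.shape
    starts = list(range(0, T, w))
    pooled = np.empty((B, len(starts), F))
    argmaxes = []
    for wi, s in enumerate(starts):
        seg = A[:, s : s + w, :]
        idx = seg.argmax(axis=1)
        pooled[:, wi, :] = np.take_along_axis(seg, idx[:, None, :], axis=1)[:, 0, :]
        argmaxes.append(idx)
    cache.update(pool_starts=starts, pool_argmax=argmaxes, conv_len=T)
    if train and cfg.dropout_conv > 0:
        mask = rng.random(pooled.shape) >= cfg.dropout_conv
        pooled = pooled * mask / (1.0 - cfg.dropout_conv)
        cache["drop_mask"] = mask
    return pooled, cache


def _branch_backward(dP, state: NetworkState, name: str, cache: dict) -> dict[str, np.ndarray]:
    cfg = state.config
    p = state.params
    F, L, D = p[f"{name}/W"].shape
    if "drop_mask" in cache:
        dP = dP * cache["drop_mask"] / (1.0 - cfg.dropout_conv)
    B = dP.shape[0]
    dA = np.zeros((B, cache["conv_len"], F))
    w = cfg.pool_window
    for wi, s in enumerate(cache["pool_starts"]):
        view = dA[:, s : s + w, :]
        np.put_along_axis(view, cache["pool_argmax"][wi][:, None, :], dP[:, wi, :][:, None, :], axis=1)
    dY = dA * cache["relu_mask"]
    grads: dict[str, np.ndarray] = {}
    if cfg.batch_norm:
        xhat = cache["xhat"]
        grads[f"{name}/gamma"] = (dY * xhat).sum(axis=(0, 1))
        grads[f"{name}/beta"] = dY.sum(axis=(0, 1))
        gamma = p[f"{name}/gamma"]
        if cache["bn_train"]:
            Nbn = dY.shape[0] * dY.shape[1]
            dxhat = dY * gamma
            dZ = (
                dxhat
                - dxhat.mean(axis=(0, 1))
                - xhat * (dxhat * xhat).mean(axis=(0, 1))
            ) * cache["inv_std"]
            del Nbn
        else:
            dZ = dY * gamma * cache["inv_std"]
    else:
        dZ = dY
    Xc = cache["Xc"]
    grads[f"{name}/W"] = np.einsum("btf,btk->fk", dZ, Xc).reshape(F, L, D)
    grads[f"{name}/b"] = dZ.sum(axis=(0, 1))
    return grads


def _lstm_forward_batched(M, Wx, Uh, b, reverse: bool) -> tuple[np.ndarray, dict]:
    B, T, X = M.shape
    H = Uh.shape[0]
    XW = M @ Wx + b
    order = list(range(T - 1, -1, -1)) if reverse else list(range(T))
    gates = {k: np.empty((T, B, H)) for k in ("i", "f", "g", "o", "c", "c_prev", "h_prev", "h")}
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    for t in order:
        a = XW[:, t] + h @ Uh
        i = _sigmoid(a[:, :H])
        f = _sigmoid(a[:, H : 2 * H])
        g = np.tanh(a[:, 2 * H : 3 * H])
        o = _sigmoid(a[:, 3 * H :])
        gates["c_prev"][t] = c
        gates["h_prev"][t] = h
        c = f * c + i * g
        h = o * np.tanh(c)
        for k, v in (("i", i), ("f", f), ("g", g), ("o", o), ("c", c), ("h", h)):
            gates[k][t] = v
    return h, {"gates": gates, "order": order, "M": M}


def _lstm_backward_batched(dh_final, dh_steps, Wx, Uh, cache) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    gates = cache["gates"]
    order = cache["order"]
    M = cache["M"]
    B, T, X = M.shape
    H = Uh.shape[0]
    dM = np.zeros_like(M)
    dWx = np.zeros_like(Wx)
    dUh = np.zeros_like(Uh)
    db = np.zeros(4 * H)
    dh_rec = dh_final.copy()
    dc = np.zeros((B, H))
    for t in reversed(order):
        dh = dh_rec
        if dh_steps is not None:
            dh = dh + dh_steps[t]
        i, f, g, o = gates["i"][t], gates["f"][t], gates["g"][t], gates["o"][t]
        c, c_prev, h_prev = gates["c"][t], gates["c_prev"][t], gates["h_prev"][t]
        tc = np.tanh(c)
        do = dh * tc
        dc = dc + dh * o * (1.0 - tc * tc)
        df = dc * c_prev
        di = dc * g
        dg = dc * i
        dc = dc * f
        da = np.concatenate(
            [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)], axis=1
        )
        db += da.sum(axis=0)
        dWx += M[:, t].T @ da
        dUh += h_prev.T @ da
        dM[:, t] += da @ Wx.T
        dh_rec = da @ Uh.T
    return dM, {"Wx": dWx, "Uh": dUh, "b": db}


def forward(
    state: NetworkState,
    Xseq: np.ndarray,
    Xstr: np.ndarray | None,
    train: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict]:
    """Full forward pass; returns logits (B,) and the backprop cache."""
    cfg = state.config
    if train and rng is None:
        raise ValueError("training-mode forward needs an RNG for dropout")
    seq_out, seq_cache = _branch_forward(Xseq, state, "seq", train, rng)
    cache: dict[str, Any] = {"seq": seq_cache}
    if cfg.use_structure:
        if Xstr is None:
            raise ValueError("model uses the structure branch but no structure input given")
        str_out, str_cache = _branch_forward(Xstr, state, "str", train, rng)
        if str_out.shape[1] != seq_out.shape[1]:
            raise ValueError("branch output lengths differ; filter lengths must match")
        merged = np.concatenate([seq_out, str_out], axis=2)
        cache["str"] = str_cache
        cache["seq_feat"] = seq_out.shape[2]
    else:
        merged = seq_out
    B, T, R = merged.shape
    if cfg.use_blstm:
        p = state.params
        hf, cache_f = _lstm_forward_batched(
            merged, p["lstm_fwd/Wx"], p["lstm_fwd/Uh"], p["lstm_fwd/b"], reverse=False
        )
        hb, cache_b = _lstm_forward_batched(
            merged, p["lstm_bwd/Wx"], p["lstm_bwd/Uh"], p["lstm_bwd/b"], reverse=True
        )
        cache["lstm_fwd"] = cache_f
        cache["lstm_bwd"] = cache_b
        if cfg.readout == "final":
            r = np.concatenate([hf, hb], axis=1)
        else:
            hs = np.concatenate([cache_f["gates"]["h"], cache_b["gates"]["h"]], axis=2)  # (T,B,2H)
            r = hs.transpose(1, 0, 2).reshape(B, -1)
    else:
        r = merged.reshape(B, -1)
    cache["merged_shape"] = (B, T, R)
    if train and cfg.dropout_out > 0:
        mask = rng.random(r.shape) >= cfg.dropout_out
        r = r * mask / (1.0 - cfg.dropout_out)
        cache["out_drop_mask"] = mask
    cache["r"] = r
    logits = r @ state.params["out/W"] + state.params["out/b"][0]
    return logits, cache


def backward(state: NetworkState, cache: dict, dlogits: np.ndarray) -> dict[str, np.ndarray]:
    """Gradients of the loss w.r.t. every parameter, given d(loss)/d(logits)."""
    cfg = state.config
    p = state.params
    r = cache["r"]
    grads: dict[str, np.ndarray] = {
        "out/W": r.T @ dlogits,
        "out/b": np.array([dlogits.sum()]),
    }
    dr = np.outer(dlogits, p["out/W"])
    if "out_drop_mask" in cache:
        dr = dr * cache["out_drop_mask"] / (1.0 - cfg.dropout_out)
    B, T, R = cache["merged_shape"]
    H = cfg.lstm_hidden
    if cfg.use_blstm:
        if cfg.readout == "final":
            dhf_final = dr[:, :H]
            dhb_final = dr[:, H:]
            dhf_steps = dhb_steps = None
        else:
            dhs = dr.reshape(B, T, 2 * H).transpose(1, 0, 2)
            dhf_steps = dhs[:, :, :H]
            dhb_steps = dhs[:, :, H:]
            dhf_final = np.zeros((B, H))
            dhb_final = np.zeros((B, H))
        dM_f, g_f = _lstm_backward_batched(
            dhf_final, dhf_steps, p["lstm_fwd/Wx"], p["lstm_fwd/Uh"], cache["lstm_fwd"]
        )
        dM_b, g_b = _lstm_backward_batched(
            dhb_final, dhb_steps, p["lstm_bwd/Wx"], p["lstm_bwd/Uh"], cache["lstm_bwd"]
        )
        for k, v in g_f.items():
            grads[f"lstm_fwd/{k}"] = v
        for k, v in g_b.items():
            grads[f"lstm_bwd/{k}"] = v
        dmerged = dM_f + dM_b
    else:
        dmerged = dr.reshape(B, T, R)
    if cfg.use_structure:
        sf = cache["seq_feat"]
        grads.update(_branch_backward(dmerged[:, :, :sf], state, "seq", cache["seq"]))
        grads.update(_branch_backward(dmerged[:, :, sf:], state, "str", cache["str"]))
    else:
        grads.update(_branch_backward(dmerged, state, "seq", cache["seq"]))
    return grads


def bce_loss_and_grad(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy from logits; gradient w.r.t. logits."""
    # stable softplus(z) - y*z
    loss = float(np.mean(np.maximum(logits, 0) - logits * y + np.log1p(np.exp(-np.abs(logits)))))
    dlogits = (_sigmoid(logits) - y) / logits.shape[0]
    return loss, dlogits


def bce_loss(probs: np.ndarray, y: np.ndarray, eps: float = 1e-12) -> float:
    p = np.clip(probs, eps, 1 - eps)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


class RmsProp:
    """RMSprop: v <- rho v + (1-rho) g^2; p <- p - lr g / (sqrt(v) + eps)."""

    def __init__(self, rho: float = 0.9, eps: float = 1e-8) -> None:
        self.rho = rho
        self.eps = eps
        self.v: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray], lr: float) -> None:
        for k, g in grads.items():
            v = self.v.get(k)
            if v is None:
                v = np.zeros_like(g)
            v = self.rho * v + (1.0 - self.rho) * g * g
            self.v[k] = v
            params[k] -= lr * g / (np.sqrt(v) + self.eps)


def predict_proba(
    state: NetworkState,
    Xseq: np.ndarray,
    Xstr: np.ndarray | None,
    batch_size: int = 512,
) -> np.ndarray:
    """Deterministic inference-mode probabilities (dropout off, batch-norm
    running statistics); independent of how the inputs are batched."""
    out = []
    for s in range(0, Xseq.shape[0], batch_size):
        logits, _ = forward(
            state,
            Xseq[s : s + batch_size],
            None if Xstr is None else Xstr[s : s + batch_size],
            train=False,
        )
        out.append(_sigmoid(logits))
    return np.concatenate(out)


def train_network(
    state: NetworkState,
    Xseq_tr: np.ndarray,
    Xstr_tr: np.ndarray | None,
    y_tr: np.ndarray,
    Xseq_va: np.ndarray,
    Xstr_va: np.ndarray | None,
    y_va: np.ndarray,
    cfg: ModelConfig,
) -> tuple[NetworkState, list[dict]]:
    """Mini-batch RMSprop training with per-epoch shuffling and early stopping.

    Stops when the validation loss has not improved for more than
    ``cfg.patience`` consecutive epochs and returns the parameters from the
    best-validation-loss epoch, together with the per-epoch history.
    """
    y_tr = np.asarray(y_tr, dtype=float)
    y_va = np.asarray(y_va, dtype=float)
    if len(np.unique(y_tr)) < 2:
        raise ValueError("training labels contain a single class")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7919]))
    opt = RmsProp(cfg.rmsprop_rho, cfg.rmsprop_eps)
    history: list[dict] = []
    best_val = np.inf
    best_state: NetworkState | None = None
    since_improve = 0
    n = Xseq_tr.shape[0]
    for epoch in range(1, cfg.max_epochs + 1):
        perm = rng.permutation(n)
        losses = []
        for s in range(0, n, cfg.batch_size):
            idx = perm[s : s + cfg.batch_size]
            logits, cache = forward(
                state,
                Xseq_tr[idx],
                None if Xstr_tr is None else Xstr_tr[idx],
                train=True,
                rng=rng,
            )
            loss, dlogits = bce_loss_and_grad(logits, y_tr[idx])
            grads = backward(state, cache, dlogits)
            opt.step(state.params, grads, cfg.learning_rate)
            losses.append(loss)
        val_probs = predict_proba(state, Xseq_va, Xstr_va)
        val_loss = bce_loss(val_probs, y_va)
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)), "val_loss": val_loss})
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_state = state.copy()
            since_improve = 0
        else:
            since_improve += 1
            if since_improve > cfg.patience:
                break
    if best_state is not None:
        state = best_state
    return state, history
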