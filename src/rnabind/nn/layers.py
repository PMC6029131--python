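"""Reference single-sample layer operations.

These are the mathematical primitives of the network — valid
cross-correlation with ReLU, windowed max-pooling and the LSTM cell —
written for clarity.  The batched training kernels in
:mod:`rnabind.nn.network` must agree with these to numerical precision;
the test suite checks that agreement against independent brute-force
oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def conv_forward(x: np.ndarray, weights: np.ndarray, biases: np.ndarray) -> np.ndarray:
    """ReLU cross-correlation of one encoded matrix with a filter bank.

    x: (P, D) encoded (padded) matrix; weights: (F, L, D); biases: (F,).
    Returns the activation map (F, P - L + 1) with
    ``A[f, i] = ReLU(sum_{l,d} w[f, l, d] * x[i + l, d] + b[f])``.
    """
    F, L, D = weights.shape
    if x.ndim != 2 or x.shape[1] != D:
        raise ValueError(f"channel mismatch: input has {x.shape[-1]} columns, filters expect {D}")
    if x.shape[0] < L:
        raise ValueError("input shorter than filter length")
    windows = sliding_window_view(x, L, axis=0)  # (T, D, L)
    flat = windows.transpose(0, 2, 1).reshape(windows.shape[0], L * D)
    z = flat @ weights.reshape(F, L * D).T + biases
    return np.maximum(z, 0.0).T


def max_pool(a: np.ndarray, window: int, stride: int | None = None) -> np.ndarray:
    """Per-filter max over consecutive windows; a trailing partial window is kept.

    a: (F, T) activation map.
    """
    if window < 1:
        raise ValueError("pool window must be >= 1")
    if stride is None:
        stride = window
    F, T = a.shape
    starts = range(0, T, stride)
    return np.stack([a[:, s : s + window].max(axis=1) for s in starts], axis=1)


@dataclass
class LstmParams:
    """Gate parameters of one LSTM direction.

    ``W_*`` map the input (H x X), ``U_*`` the previous hidden state
    (H x H), ``b_*`` are biases (H,), for the forget, input, candidate and
    output gates.
    """

    W_f: np.ndarray
    W_i: np.ndarray
    W_c: np.ndarray
    W_o: np.ndarray
    U_f: np.ndarray
    U_i: np.ndarray
    U_c: np.ndarray
    U_o: np.ndarray
    b_f: np.ndarray
    b_i: np.ndarray
    b_c: np.ndarray
    b_o: np.ndarray

    def __post_init__(self) -> None:
        H, X = self.W_f.shape
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name.startswith("W") and v.shape != (H, X):
                raise ValueError(f"{f.name} shape {v.shape} != {(H, X)}")
            if f.name.startswith("U") and v.shape != (H, H):
                raise ValueError(f"{f.name} shape {v.shape} != {(H, H)}")
            if f.name.startswith("b") and v.shape != (H,):
                raise ValueError(f"{f.name} shape {v.shape} != {(H,)}")

    @property
    def hidden_size(self) -> int:
        return self.W_f.shape[0]

    @property
    def input_size(self) -> int:
        return self.W_f.shape[1]


def lstm_step(
    x_t: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray, p: LstmParams
) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM cell update: gates from the input and the previous state.

    f = sigma(W_f x + U_f h + b_f); i likewise; the cell state is
    c = f * c_prev + i * tanh(W_c x + U_c h + b_c); the hidden state is
    h = sigma(W_o x + U_o h + b_o) * tanh(c).
    """
    if x_t.shape != (p.input_size,):
        raise ValueError(f"input shape {x_t.shape} != ({p.input_size},)")
    if h_prev.shape != (p.hidden_size,) or c_prev.shape != (p.hidden_size,):
        raise ValueError("state shape mismatch")
    f = _sigmoid(p.W_f @ x_t + p.U_f @ h_prev + p.b_f)
    i = _sigmoid(p.W_i @ x_t + p.U_i @ h_prev + p.b_i)
    g = np.tanh(p.W_c @ x_t + p.U_c @ h_prev + p.b_c)
    o = _sigmoid(p.W_o @ x_t + p.U_o @ h_prev + p.b_o)
    c_t = f * c_prev + i * g
    h_t = o * np.tanh(c_t)
    return h_t, c_t


def lstm_run(xs: np.ndarray, p: LstmParams) -> np.ndarray:
    """Run one direction from zero initial states; returns the final hidden state."""
    H = p.hidden_size
    h = np.zeros(H)
    c = np.zeros(H)
    for t in range(xs.shape[0]):
        h, c = lstm_step(xs[t], h, c, p)
    return h


def blstm_forward(xs: np.ndarray, fwd: LstmParams, bwd: LstmParams) -> np.ndarray:
    """Bidirectional sweep; returns the concatenated final hidden states (2H,)."""
    if xs.ndim != 2 or xs.shape[0] < 1:
        raise ValueError("input must be a non-empty (T, X) array")
    h_f = lstm_run(xs, fwd)
    h_b = lstm_run(xs[::-1], bwd)
    return np.concatenate([h_f, h_b])
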