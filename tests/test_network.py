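"""Numeric core of the network against brute-force oracles, plus the
training/prediction contracts."""

import numpy as np
import pytest

from rnabind.encoding import encode_sequence
from rnabind.nn.layers import LstmParams, blstm_forward, conv_forward, lstm_step, lstm_run, max_pool
from rnabind.nn.network import (
    ModelConfig,
    backward,
    bce_loss_and_grad,
    build_network,
    forward,
    predict_proba,
    train_network,
)

# --- oracles ---------------------------------------------------------------


def conv_oracle(x, w, b):
    F, L, D = w.shape
    T = x.shape[0] - L + 1
    out = np.zeros((F, T))
    for f in range(F):
        for i in range(T):
            s = b[f]
            for l in range(L):
                for d in range(D):
                    s += w[f, l, d] * x[i + l, d]
            out[f, i] = max(s, 0.0)
    return out


def lstm_step_oracle(x, h, c, p):
    H = p.hidden_size
    h_new = np.zeros(H)
    c_new = np.zeros(H)
    for j in range(H):
        af = p.b_f[j] + p.W_f[j] @ x + p.U_f[j] @ h
        ai = p.b_i[j] + p.W_i[j] @ x + p.U_i[j] @ h
        ac = p.b_c[j] + p.W_c[j] @ x + p.U_c[j] @ h
        ao = p.b_o[j] + p.W_o[j] @ x + p.U_o[j] @ h
        sig = lambda v: 1.0 / (1.0 + np.exp(-v))
        c_new[j] = sig(af) * c[j] + sig(ai) * np.tanh(ac)
        h_new[j] = sig(ao) * np.tanh(c_new[j])
    return h_new, c_new


def random_lstm_params(rng, X, H):
    kw = {}
    for g in "fico":
        kw[f"W_{g}"] = rng.normal(size=(H, X))
        kw[f"U_{g}"] = rng.normal(size=(H, H))
        kw[f"b_{g}"] = rng.normal(size=H)
    return LstmParams(**kw)


# --- convolution -----------------------------------------------------------


def test_conv_zero_weights():
    x = encode_sequence("ACGUACGU", 3)
    out = conv_forward(x, np.zeros((2, 3, 4)), np.zeros(2))
    assert out.shape == (2, x.shape[0] - 3 + 1)
    assert (out == 0).all()


def test_conv_matched_one_hot_pattern():
    """A filter holding the one-hot pattern of GAU scores 3 at the aligned
    interior position of GAU."""
    x = encode_sequence("GAU", 3)
    w = np.zeros((1, 3, 4))
    w[0, 0, 2] = w[0, 1, 0] = w[0, 2, 3] = 1.0  # G, A, U columns
    out = conv_forward(x, w, np.zeros(1))
    assert out.shape == (1, 5)
    assert out[0, 2] == pytest.approx(3.0)
    assert out[0].max() == pytest.approx(3.0)


def test_conv_matches_oracle(rng):
    for _ in range(5):
        x = rng.normal(size=(rng.integers(8, 20), 4))
        w = rng.normal(size=(3, 5, 4))
        b = rng.normal(size=3)
        np.testing.assert_allclose(conv_forward(x, w, b), conv_oracle(x, w, b), atol=1e-6)


def test_conv_channel_mismatch():
    with pytest.raises(ValueError):
        conv_forward(np.zeros((10, 6)), np.zeros((2, 3, 4)), np.zeros(2))


# --- pooling ---------------------------------------------------------------


def test_max_pool_contracts():
    a = np.array([[1.0, 5.0, 2.0, 0.0]])
    np.testing.assert_array_equal(max_pool(a, 1), a)  # window 1 = identity
    np.testing.assert_array_equal(max_pool(a, 2), [[5.0, 2.0]])
    tail = max_pool(np.arange(5.0)[None, :], 2)
    np.testing.assert_array_equal(tail, [[1.0, 3.0, 4.0]])  # partial tail kept


# --- LSTM ------------------------------------------------------------------


def test_lstm_step_zero_everything():
    p = random_lstm_params(np.random.default_rng(0), 3, 2)
    for f in ("W_f", "W_i", "W_c", "W_o", "U_f", "U_i", "U_c", "U_o"):
        getattr(p, f)[:] = 0.0
    for f in ("b_f", "b_i", "b_c", "b_o"):
        getattr(p, f)[:] = 0.0
    h, c = lstm_step(np.zeros(3), np.zeros(2), np.zeros(2), p)
    np.testing.assert_allclose(c, 0.0)
    np.testing.assert_allclose(h, 0.0)


def test_lstm_step_saturated_forget_gate():
    """With b_f = +100 and everything else zero, the cell copies c_prev and
    h = 0.5 * tanh(1) ~ 0.38080."""
    zero = lambda *s: np.zeros(s)
    p = LstmParams(
        W_f=zero(1, 1), W_i=zero(1, 1), W_c=zero(1, 1), W_o=zero(1, 1),
        U_f=zero(1, 1), U_i=zero(1, 1), U_c=zero(1, 1), U_o=zero(1, 1),
        b_f=np.array([100.0]), b_i=zero(1), b_c=zero(1), b_o=zero(1),
    )
    h, c = lstm_step(np.zeros(1), np.zeros(1), np.ones(1), p)
    assert c[0] == pytest.approx(1.0, abs=1e-4)
    assert h[0] == pytest.approx(0.5 * np.tanh(1.0), abs=1e-4)


def test_lstm_step_matches_oracle(rng):
    p = random_lstm_params(rng, 4, 3)
    for _ in range(5):
        x, h, c = rng.normal(size=4), rng.normal(size=3), rng.normal(size=3)
        got = lstm_step(x, h, c, p)
        want = lstm_step_oracle(x, h, c, p)
        np.testing.assert_allclose(got[0], want[0], atol=1e-6)
        np.testing.assert_allclose(got[1], want[1], atol=1e-6)


def test_blstm_single_step_and_palindrome(rng):
    fwd = random_lstm_params(rng, 3, 2)
    bwd = random_lstm_params(rng, 3, 2)
    x = rng.normal(size=(1, 3))
    out = blstm_forward(x, fwd, bwd)
    np.testing.assert_allclose(out[:2], lstm_step(x[0], np.zeros(2), np.zeros(2), fwd)[0])
    np.testing.assert_allclose(out[2:], lstm_step(x[0], np.zeros(2), np.zeros(2), bwd)[0])
    # palindromic input, shared parameters: the two halves coincide
    pal = np.stack([x[0], rng.normal(size=3), x[0]])
    pal[2] = pal[0]
    out = blstm_forward(pal, fwd, fwd)
    np.testing.assert_allclose(out[:2], out[2:])


def test_blstm_matches_composed_oracle(rng):
    fwd = random_lstm_params(rng, 3, 2)
    bwd = random_lstm_params(rng, 3, 2)
    xs = rng.normal(size=(6, 3))
    got = blstm_forward(xs, fwd, bwd)
    h = np.zeros(2)
    c = np.zeros(2)
    for t in range(6):
        h, c = lstm_step_oracle(xs[t], h, c, fwd)
    np.testing.assert_allclose(got[:2], h, atol=1e-6)
    h = np.zeros(2)
    c = np.zeros(2)
    for t in range(5, -1, -1):
        h, c = lstm_step_oracle(xs[t], h, c, bwd)
    np.testing.assert_allclose(got[2:], h, atol=1e-6)


def test_batched_lstm_agrees_with_reference_cell(rng):
    """The packed training-time LSTM equals the per-gate reference cell."""
    cfg = ModelConfig(input_length=15, n_filters_seq=4, n_filters_struct=4,
                      filter_len_seq=5, filter_len_struct=5, lstm_hidden=6, seed=9)
    state = build_network(cfg)
    from rnabind.nn.network import _lstm_forward_batched

    M = rng.normal(size=(3, 7, 8))
    hf, _ = _lstm_forward_batched(
        M, state.params["lstm_fwd/Wx"], state.params["lstm_fwd/Uh"],
        state.params["lstm_fwd/b"], reverse=False,
    )
    p = state.lstm_params("fwd")
    for bi in range(3):
        np.testing.assert_allclose(hf[bi], lstm_run(M[bi], p), atol=1e-10)


# --- architecture and shapes ----------------------------------------------


def test_build_shapes_and_seeded_init():
    cfg = ModelConfig(seed=11)
    s1 = build_network(cfg)
    s2 = build_network(cfg)
    assert s1.params["seq/W"].shape == (16, 10, 4)
    assert s1.params["str/W"].shape == (16, 10, 6)
    for k in s1.params:
        np.testing.assert_array_equal(s1.params[k], s2.params[k])
    # conv output 110 positions, pooled ceil(110/3) = 37, merged 37 x 32
    logits, cache = forward(s1, np.full((2, 119, 4), 0.25), np.full((2, 119, 6), 1 / 6))
    assert cache["merged_shape"] == (2, 37, 32)
    assert logits.shape == (2,)


def test_gradients_match_numerical(rng):
    """Analytic backprop equals central finite differences on a tiny net."""
    cfg = ModelConfig(
        n_filters_seq=3, n_filters_struct=3, filter_len_seq=4, filter_len_struct=4,
        pool_window=2, lstm_hidden=4, dropout_conv=0.0, dropout_out=0.0,
        input_length=12, seed=3,
    )
    state = build_network(cfg)
    B = 5
    Xs = rng.random((B, 12 + 6, 4))
    Xt = rng.random((B, 12 + 6, 6))
    y = rng.integers(0, 2, B).astype(float)

    def loss():
        logits, _ = forward(state, Xs, Xt, train=True, rng=np.random.default_rng(1))
        return bce_loss_and_grad(logits, y)[0]

    logits, cache = forward(state, Xs, Xt, train=True, rng=np.random.default_rng(1))
    _, dlog = bce_loss_and_grad(logits, y)
    grads = backward(state, cache, dlog)
    eps = 1e-6
    check_rng = np.random.default_rng(7)
    for k, g in grads.items():
        p = state.params[k]
        flat = p.reshape(-1)
        for idx in check_rng.choice(flat.size, size=min(4, flat.size), replace=False):
            old = flat[idx]
            flat[idx] = old + eps
            lp = loss()
            flat[idx] = old - eps
            lm = loss()
            flat[idx] = old
            num = (lp - lm) / (2 * eps)
            assert g.reshape(-1)[idx] == pytest.approx(num, abs=1e-6, rel=1e-4), k


# --- training contracts ----------------------------------------------------


def _toy_data(rng, n=60, length=12):
    # class 1 = all-A reads, class 0 = all-U reads: trivially separable
    Xs = np.empty((n, length + 6, 4))
    y = rng.integers(0, 2, n)
    from rnabind.encoding import encode_sequence

    for i in range(n):
        Xs[i] = encode_sequence(("A" if y[i] else "U") * length, 4)
    return Xs, y.astype(float)


def _tiny_cfg(**kw):
    base = dict(
        n_filters_seq=4, filter_len_seq=4, pool_window=2, lstm_hidden=4,
        input_length=12, use_structure=False, batch_size=20, max_epochs=3,
        patience=5, seed=0,
    )
    base.update(kw)
    return ModelConfig(**base)


def test_train_rejects_single_class(rng):
    Xs, y = _toy_data(rng)
    cfg = _tiny_cfg()
    with pytest.raises(ValueError):
        train_network(build_network(cfg), Xs, None, np.ones_like(y), Xs, None, y, cfg)


def test_zero_learning_rate_leaves_parameters_unchanged(rng):
    Xs, y = _toy_data(rng)
    # dropout and batch-norm off so the train-mode loss itself is deterministic
    cfg = _tiny_cfg(learning_rate=0.0, max_epochs=2, dropout_conv=0.0,
                    dropout_out=0.0, batch_norm=False)
    state = build_network(cfg)
    before = {k: v.copy() for k, v in state.params.items()}
    trained, history = train_network(state, Xs, None, y, Xs, None, y, cfg)
    for k in before:
        np.testing.assert_array_equal(trained.params[k], before[k])
    losses = [h["train_loss"] for h in history]
    assert max(losses) - min(losses) < 1e-6  # flat loss


def test_patience_zero_stops_at_first_non_improving_epoch(rng):
    Xs, y = _toy_data(rng)
    # lr 0 means the validation loss never improves after epoch 1
    cfg = _tiny_cfg(learning_rate=0.0, patience=0, max_epochs=10,
                    dropout_conv=0.0, dropout_out=0.0, batch_norm=False)
    _, history = train_network(build_network(cfg), Xs, None, y, Xs, None, y, cfg)
    assert len(history) == 2


def test_training_learns_separable_data(rng):
    Xs, y = _toy_data(rng, n=80)
    cfg = _tiny_cfg(max_epochs=15)
    state, history = train_network(build_network(cfg), Xs, None, y, Xs, None, y, cfg)
    best = min(h["val_loss"] for h in history)
    assert best < history[0]["val_loss"]
    probs = predict_proba(state, Xs, None)
    from rnabind.evaluation import auc

    assert auc(y, probs) > 0.95


def test_prediction_determinism_and_batch_independence(trained_small):
    ds, results = trained_small
    test = ds.split("test")
    p1 = results.predict(test.sequences, test.structures)
    p2 = results.predict(test.sequences, test.structures)
    np.testing.assert_array_equal(p1, p2)
    assert ((p1 > 0) & (p1 < 1)).all()
    # permuting a batch permutes outputs identically (no cross-sample leakage)
    perm = np.random.default_rng(0).permutation(len(test.sequences))
    p3 = results.predict(
        [test.sequences[i] for i in perm],
        [test.structures[i] for i in perm],
    )
    np.testing.assert_allclose(p3, p1[perm], atol=1e-12)


def test_checkpoint_round_trip(tmp_path, trained_small):
    ds, results = trained_small
    path = tmp_path / "model.json"
    results.save(path)
    from rnabind.model import BindingSiteResults

    loaded = BindingSiteResults.load(path)
    test = ds.split("test")
    np.testing.assert_allclose(
        loaded.predict(test.sequences, test.structures),
        results.predict(test.sequences, test.structures),
        atol=1e-12,
    )
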