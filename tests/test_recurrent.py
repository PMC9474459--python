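"""Recurrent baseline cells: printed recursions, BPTT, training."""

import numpy as np
import pytest

from tetramap.calibration import (BaselineSpec, GruParams, LstmParams,
                                  RnnParams, baseline_cell_forward,
                                  train_baseline)
from tetramap.calibration.recurrent import _init_params, gradients


def _zeros_gru(H=4):
    z = np.zeros
    return GruParams(w_rh=z((H, H)), w_rx=z(H), w_zh=z((H, H)), w_zx=z(H),
                     w_hh=z((H, H)), w_hx=z(H), v=z(H))


def _zeros_lstm(H=4):
    z = np.zeros
    return LstmParams(w_fh=z((H, H)), w_fx=z(H), b_f=z(H),
                      w_ih=z((H, H)), w_ix=z(H), b_i=z(H),
                      w_ch=z((H, H)), w_cx=z(H), b_c=z(H),
                      w_oh=z((H, H)), w_ox=z(H), b_o=z(H), v=z(H))


# --------------------------------------------------------------------------
# forward hand values


def test_gru_printed_update_hand_value():
    # all weights zero, h0=1: r=z=sigma(0)=0.5, h~=tanh(0)=0,
    # h1 = (1-z)*r*h0 + z*h~ = 0.5*0.5*1 = 0.25
    fp = baseline_cell_forward(_zeros_gru(), np.array([[0.7]]),
                               h0=np.ones((1, 4)))
    assert np.allclose(fp.final, 0.25)


def test_gru_standard_update_hand_value():
    # standard variant: h1 = (1-z)*h0 + z*h~ = 0.5*1 + 0 = 0.5
    fp = baseline_cell_forward(_zeros_gru(), np.array([[0.7]]),
                               h0=np.ones((1, 4)), standard_gru=True)
    assert np.allclose(fp.final, 0.5)


def test_rnn_zero_weights_constant_state():
    p = RnnParams(u=np.zeros(4), w=np.zeros((4, 4)), v=np.zeros(4))
    fp = baseline_cell_forward(p, np.array([[0.1, 0.9, 0.5]]))
    assert np.allclose(fp.hidden, np.tanh(0.0))


def test_lstm_perfect_memory_gate_limit():
    # bias the forget gate strongly open and the input gate closed:
    # C_t stays (numerically) at C_0
    p = _zeros_lstm()
    p.b_f += 50.0   # f ~ 1
    p.b_i -= 50.0   # i ~ 0
    c0 = np.full((1, 4), 0.37)
    fp = baseline_cell_forward(p, np.array([[0.2, 0.4, 0.6]]), c0=c0)
    assert np.allclose(fp.cell[:, -1], 0.37, atol=1e-10)


def test_forward_accepts_1d_sequence():
    p = _init_params("RNN", 4, np.random.default_rng(0))
    fp = baseline_cell_forward(p, np.array([0.1, 0.2, 0.3]))
    assert fp.hidden.shape == (1, 3, 4)


# --------------------------------------------------------------------------
# gradients vs finite differences


@pytest.mark.parametrize("kind", ["RNN", "LSTM", "GRU"])
def test_bptt_matches_finite_differences(kind):
    rng = np.random.default_rng(1)
    X = rng.random((4, 8))
    y = rng.random(4)
    params = _init_params(kind, 3, np.random.default_rng(2))

    def loss():
        fp = baseline_cell_forward(params, X)
        out = fp.final @ params.v + params.c
        return np.abs(out - y).mean()

    fp = baseline_cell_forward(params, X)
    out = fp.final @ params.v + params.c
    g = gradients(params, X, np.sign(out - y) / len(y))

    eps = 1e-6
    for name, arr in params.arrays().items():
        numeric = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            if name == "c":
                orig = params.c
                params.c = orig + eps
                up = loss()
                params.c = orig - eps
                down = loss()
                params.c = orig
            else:
                orig = arr[idx]
                arr[idx] = orig + eps
                up = loss()
                arr[idx] = orig - eps
                down = loss()
                arr[idx] = orig
            numeric[idx] = (up - down) / (2 * eps)
        assert np.abs(numeric - g[name]).max() < 1e-7, name


def test_gru_standard_variant_gradients():
    rng = np.random.default_rng(3)
    X = rng.random((3, 8))
    y = rng.random(3)
    params = _init_params("GRU", 3, np.random.default_rng(4))

    fp = baseline_cell_forward(params, X, standard_gru=True)
    out = fp.final @ params.v + params.c
    g = gradients(params, X, np.sign(out - y) / len(y), standard_gru=True)

    eps = 1e-6
    arr = params.w_zh
    numeric = np.zeros_like(arr)
    it = np.nditer(arr, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = arr[idx]
        vals = []
        for delta in (eps, -eps):
            arr[idx] = orig + delta
            f = baseline_cell_forward(params, X, standard_gru=True)
            o = f.final @ params.v + params.c
            vals.append(np.abs(o - y).mean())
        arr[idx] = orig
        numeric[idx] = (vals[0] - vals[1]) / (2 * eps)
    assert np.abs(numeric - g["w_zh"]).max() < 1e-7


# --------------------------------------------------------------------------
# training


def test_train_baseline_deterministic(small_calibration):
    ds, _ = small_calibration
    training, validation = ds.split(0.25, seed=0)
    spec = BaselineSpec(kind="RNN", hidden=8, epochs=40, seed=1)
    a = train_baseline("RNN", training, spec, validation=validation)
    b = train_baseline("RNN", training, spec, validation=validation)
    assert a.training_metrics == b.training_metrics
    assert a.validation_metrics == b.validation_metrics


def test_train_baseline_zero_epochs(small_calibration):
    ds, _ = small_calibration
    spec = BaselineSpec(kind="GRU", hidden=8, epochs=0, seed=2)
    fit = train_baseline("GRU", ds, spec)
    assert len(fit.loss_history) == 0
    assert np.isfinite(fit.predict(ds)).all()


def test_train_baseline_loss_improves(small_calibration):
    ds, _ = small_calibration
    spec = BaselineSpec(kind="LSTM", hidden=16, epochs=150, seed=3)
    fit = train_baseline("LSTM", ds, spec)
    assert fit.loss_history[-1] < fit.loss_history[0]


def test_baseline_spec_validation():
    with pytest.raises(ValueError):
        BaselineSpec(kind="CNN")
    with pytest.raises(ValueError):
        BaselineSpec(hidden=0)
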