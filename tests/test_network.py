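"""Feed-forward MAP network: Adam, determinism, recovery, artifacts."""

import numpy as np
import pandas as pd
import pytest

from tetramap.calibration import (AdamState, DEFAULT_FEATURES, MapNetwork,
                                  MapNetworkResults, NetworkSpec, adam_step,
                                  relu, relu_grad, train_dlnn)
from tetramap.containers import CalibrationDataset
from tetramap.registry import COMPOUND_NAMES


# --------------------------------------------------------------------------
# ReLU and Adam


def test_relu_values_and_grad():
    assert relu(-3.0) == 0.0 and relu_grad(-3.0) == 0.0
    assert relu(5.0) == 5.0 and relu_grad(5.0) == 1.0
    assert relu(0.0) == 0.0 and relu_grad(0.0) == 0.0  # x <= 0 branch


def test_adam_first_step_magnitude():
    spec = NetworkSpec()
    state, dw = adam_step(AdamState(), np.array([1.0]), spec)
    assert abs(abs(dw[0]) - spec.learning_rate) < 1e-6
    assert dw[0] < 0  # descends along +1 gradient
    assert state.t == 1


def test_adam_sign_follows_gradient():
    spec = NetworkSpec()
    _, dw = adam_step(AdamState(), np.array([-2.0]), spec)
    assert dw[0] == pytest.approx(0.001, abs=1e-6)


def test_adam_constant_gradient_second_step():
    spec = NetworkSpec()
    state, dw1 = adam_step(AdamState(), np.array([1.0]), spec)
    state, dw2 = adam_step(state, np.array([1.0]), spec)
    # with constant gradient, bias correction keeps |dw| at the rate
    assert dw2[0] == pytest.approx(-0.001, abs=1e-6)


def test_adam_closed_form_ten_steps():
    spec = NetworkSpec()
    state = AdamState()
    for _ in range(10):
        state, dw = adam_step(state, np.array([1.0]), spec)
        assert abs(abs(dw[0]) - 0.001) < 1e-6


def test_adam_stale_state_rejected():
    with pytest.raises(ValueError):
        adam_step(AdamState(t=-1), np.array([1.0]), NetworkSpec())


# --------------------------------------------------------------------------
# training mechanics


def _linear_dataset(n=500, seed=20, sigma=50.0):
    """MAP = 2500*Ia + 300 + noise, composition otherwise unstructured."""
    rng = np.random.default_rng(seed)
    # wide Ia spread so the 2500*Ia signal dominates the sigma=50 noise
    # (a symmetric Dirichlet would cap attainable R-squared near 0.9)
    ia = rng.uniform(0.0, 0.8, n)
    rest = rng.dirichlet(np.ones(14), size=n) * (1.0 - ia)[:, None]
    comp = np.column_stack([ia, rest])
    frame = pd.DataFrame(comp, columns=list(COMPOUND_NAMES))
    y = 2500.0 * frame["Ia"] + 300.0 + rng.normal(0.0, sigma, n)
    return CalibrationDataset(abundances=frame,
                              map_mm=pd.Series(y, name="MAP_mm"))


def test_zero_epochs_returns_initial_network():
    ds = _linear_dataset(n=50)
    spec = NetworkSpec(hidden_layers=2, neurons=8, epochs=0, seed=1)
    res = MapNetwork.from_dataset(ds, spec=spec).fit()
    preds = res.predict(ds)
    assert np.isfinite(preds).all()
    assert len(res.loss_history) == 0


def test_same_seed_identical_weights():
    ds = _linear_dataset(n=80)
    spec = NetworkSpec(hidden_layers=2, neurons=8, epochs=30, seed=5)
    r1 = MapNetwork.from_dataset(ds, spec=spec).fit()
    r2 = MapNetwork.from_dataset(ds, spec=spec).fit()
    for (w1, b1), (w2, b2) in zip(r1.params, r2.params):
        assert np.array_equal(w1, w2) and np.array_equal(b1, b2)


def test_duplicate_rows_identical_predictions():
    ds = _linear_dataset(n=60)
    spec = NetworkSpec(hidden_layers=2, neurons=8, epochs=30, seed=2)
    res = train_dlnn(ds, spec)
    row = ds.abundances.iloc[[0]]
    doubled = pd.concat([row, row], ignore_index=True)
    preds = res.predict(doubled)
    assert preds[0] == preds[1]


def test_training_loss_decreases_after_warmup():
    ds = _linear_dataset(n=300, sigma=0.0)  # noiseless, in model class
    spec = NetworkSpec(hidden_layers=2, neurons=32, epochs=400, seed=3)
    res = train_dlnn(ds, spec)
    warm = res.loss_history[50]
    assert res.loss_history[-1] <= warm
    # monotone-capacity reading: the best loss so far keeps improving
    assert res.loss_history[300:].min() <= res.loss_history[50:150].min()


def test_linear_signal_recovery():
    ds = _linear_dataset(n=500, seed=21)
    training, validation = ds.split(0.25, seed=0)
    spec = NetworkSpec(hidden_layers=4, neurons=64, epochs=1200, seed=0)
    res = train_dlnn(training, spec, validation=validation)
    assert res.validation_metrics.r2 >= 0.9


def test_minibatch_training_runs():
    ds = _linear_dataset(n=120)
    spec = NetworkSpec(hidden_layers=2, neurons=16, epochs=20,
                       minibatch=32, seed=4)
    res = train_dlnn(ds, spec)
    assert np.isfinite(res.loss_history).all()


def test_clamp_nonnegative_flag():
    ds = _linear_dataset(n=60)
    spec = NetworkSpec(hidden_layers=2, neurons=8, epochs=0, seed=8)
    res = MapNetwork.from_dataset(ds, spec=spec).fit()
    raw = res.predict(ds)
    clamped = res.predict(ds, clamp_nonnegative=True)
    assert (clamped >= 0).all()
    assert np.allclose(np.clip(raw, 0, None), clamped)


def test_missing_feature_column_schema_error():
    from tetramap.errors import SchemaError

    ds = _linear_dataset(n=60)
    spec = NetworkSpec(hidden_layers=2, neurons=8, epochs=5, seed=6)
    res = train_dlnn(ds, spec)
    bad = ds.abundances.drop(columns=["Ic"])
    with pytest.raises(SchemaError, match="Ic"):
        res.predict(bad)


def test_artifact_round_trip(tmp_path):
    ds = _linear_dataset(n=80)
    spec = NetworkSpec(hidden_layers=2, neurons=8, epochs=25, seed=7)
    res = train_dlnn(ds, spec)
    path = tmp_path / "model.json"
    res.save(path)
    loaded = MapNetworkResults.load(path)
    assert np.array_equal(res.predict(ds), loaded.predict(ds))
    assert loaded.spec == res.spec
    assert loaded.feature_names == res.feature_names


def test_spec_validation():
    with pytest.raises(ValueError):
        NetworkSpec(learning_rate=0.0)
    with pytest.raises(ValueError):
        NetworkSpec(rho1=1.0)
    with pytest.raises(ValueError):
        NetworkSpec(epochs=-1)


def test_default_features_are_eight():
    assert len(DEFAULT_FEATURES) == 8
    assert "Ib" not in DEFAULT_FEATURES
    assert "Ia" in DEFAULT_FEATURES and "Ic" in DEFAULT_FEATURES
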