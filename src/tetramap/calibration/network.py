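"""Deep feed-forward MAP calibration network, trained from scratch.

Architecture: the input layer takes the chosen compound fractions (eight
by default), four ReLU hidden layers of equal width follow, and a single
linear output unit emits mean annual precipitation.  Training minimises
the mean absolute error with the Adam optimizer:

    a <- rho1 * a + (1 - rho1) * g          (first moment)
    b <- rho2 * b + (1 - rho2) * g (.) g    (second moment)
    a_c = a / (1 - rho1^t),  b_c = b / (1 - rho2^t)
    dw  = -lambda * a_c / (sqrt(b_c) + eps)
    w  <- w + dw

with lambda = 0.001, rho1 = 0.9, rho2 = 0.999, eps = 1e-8.

Targets are standardized internally (z-scored on the training set) and
rescaled to mm on output: with a learning rate capped at 1e-3 per step a
raw-mm output scale is unreachable within the printed epoch budgets,
whereas on the standardized scale the same budgets converge.  All fit
metrics are reported in mm.  Given a fixed seed, training is
bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ..containers import CalibrationDataset
from ..errors import DivergenceError, SchemaError
from .dataset import DEFAULT_FEATURES
from .metrics import FitMetrics, evaluate

__all__ = ["relu", "relu_grad", "AdamState", "adam_step", "NetworkSpec",
           "MapNetwork", "MapNetworkResults", "train_dlnn", "predict_map"]

_ARTIFACT_VERSION = 1


def relu(x):
    """Rectified linear unit max(0, x)."""
    return np.maximum(np.asarray(x, dtype=float), 0.0)


def relu_grad(x):
    """ReLU derivative: 1 for x > 0, 0 for x <= 0."""
    return (np.asarray(x, dtype=float) > 0).astype(float)


@dataclass(frozen=True)
class NetworkSpec:
    """Hyperparameters of the feed-forward calibration network."""

    hidden_layers: int = 4
    neurons: int = 160
    epochs: int = 1000
    learning_rate: float = 0.001
    rho1: float = 0.9
    rho2: float = 0.999
    epsilon: float = 1e-8
    minibatch: int | None = None    # None = full batch
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not (0 < self.rho1 < 1 and 0 < self.rho2 < 1):
            raise ValueError("decay rates must lie in (0, 1)")
        if self.epochs < 0 or self.hidden_layers < 1 or self.neurons < 1:
            raise ValueError("epochs >= 0 and positive layer sizes required")
        if self.minibatch is not None and self.minibatch < 1:
            raise ValueError("minibatch must be >= 1 when given")


@dataclass
class AdamState:
    """First/second moment accumulators and the step counter."""

    a: object = None     # first moment (matches gradient structure)
    b: object = None     # second moment
    t: int = 0


def adam_step(state: AdamState, gradient, spec: NetworkSpec
              ) -> tuple[AdamState, np.ndarray]:
    """One Adam update for a single tensor; returns (new state, dw).

    The state starts at a = b = 0, t = 0; each call advances t.
    """
    if state.t < 0:
        raise ValueError("stale Adam state: step counter must be >= 0")
    g = np.asarray(gradient, dtype=float)
    a = np.zeros_like(g) if state.a is None else state.a
    b = np.zeros_like(g) if state.b is None else state.b
    t = state.t + 1
    a = spec.rho1 * a + (1.0 - spec.rho1) * g
    b = spec.rho2 * b + (1.0 - spec.rho2) * (g * g)
    a_c = a / (1.0 - spec.rho1 ** t)
    b_c = b / (1.0 - spec.rho2 ** t)
    dw = -spec.learning_rate * a_c / (np.sqrt(b_c) + spec.epsilon)
    return AdamState(a=a, b=b, t=t), dw


def _init_params(rng: np.random.Generator, sizes: list[int]
                 ) -> list[tuple[np.ndarray, np.ndarray]]:
    """He-scaled Gaussian weights, zero biases, per layer."""
    params = []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        w = rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / fan_in)
        params.append((w, np.zeros(fan_out)))
    return params


def _forward(params, X):
    """Pre-activations and activations of every layer."""
    acts = [X]
    pre = []
    a = X
    for w, b in params[:-1]:
        z = a @ w + b
        pre.append(z)
        a = relu(z)
        acts.append(a)
    w, b = params[-1]
    out = (a @ w + b).ravel()
    return out, pre, acts


def _backward(params, pre, acts, dloss_dout):
    """Gradients of the loss w.r.t. every weight and bias."""
    grads = [None] * len(params)
    delta = dloss_dout[:, None]                      # (n, 1)
    for i in range(len(params) - 1, -1, -1):
        w, _ = params[i]
        grads[i] = (acts[i].T @ delta, delta.sum(axis=0))
        if i > 0:
            delta = (delta @ w.T) * relu_grad(pre[i - 1])
    return grads


class MapNetwork:
    """brGDGT -> MAP calibration model (statsmodels-style).

    Parameters
    ----------
    endog : array-like
        Observed MAP in mm/yr.
    exog : array-like
        Feature matrix (n, k) of compound fractional abundances.
    spec : NetworkSpec
        Architecture and optimizer settings.
    feature_names : sequence of str
        Compound names in column order.

    Use :meth:`from_dataset` to build from a :class:`CalibrationDataset`,
    then :meth:`fit` to train; prediction, metrics and serialization live
    on the returned :class:`MapNetworkResults`.
    """

    def __init__(self, endog, exog, spec: NetworkSpec | None = None,
                 feature_names=DEFAULT_FEATURES):
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim != 2 or len(self.endog) != len(self.exog):
            raise ValueError("exog must be (n, k) aligned with endog")
        if len(self.endog) == 0:
            raise ValueError("training data is empty")
        self.spec = spec or NetworkSpec()
        self.feature_names = tuple(feature_names)
        if len(self.feature_names) != self.exog.shape[1]:
            raise ValueError("feature_names length must match exog columns")

    @classmethod
    def from_dataset(cls, ds: CalibrationDataset,
                     features=DEFAULT_FEATURES,
                     spec: NetworkSpec | None = None) -> "MapNetwork":
        return cls(ds.map_mm.to_numpy(dtype=float), ds.features(features),
                   spec=spec, feature_names=features)

    def fit(self) -> "MapNetworkResults":
        """Train with (mini)batch Adam on MAE; deterministic given seed."""
        spec = self.spec
        rng = np.random.default_rng(spec.seed)
        n, k = self.exog.shape
        sizes = [k] + [spec.neurons] * spec.hidden_layers + [1]
        params = _init_params(rng, sizes)

        y_mean = float(self.endog.mean())
        y_sd = float(self.endog.std())
        if y_sd == 0:
            y_sd = 1.0
        y = (self.endog - y_mean) / y_sd

        states = [AdamState() for _ in range(2 * len(params))]
        batch = n if spec.minibatch is None else min(spec.minibatch, n)
        loss_history = []
        for epoch in range(spec.epochs):
            order = np.arange(n) if batch == n else rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, batch):
                idx = order[start:start + batch]
                out, pre, acts = _forward(params, self.exog[idx])
                resid = out - y[idx]
                epoch_loss += float(np.abs(resid).sum())
                dldo = np.sign(resid) / len(idx)
                grads = _backward(params, pre, acts, dldo)
                for i, (gw, gb) in enumerate(grads):
                    states[2 * i], dw = adam_step(states[2 * i], gw, spec)
                    states[2 * i + 1], db = adam_step(states[2 * i + 1], gb, spec)
                    w, b = params[i]
                    params[i] = (w + dw, b + db)
            epoch_loss /= n
            if not np.isfinite(epoch_loss):
                raise DivergenceError(f"non-finite loss at epoch {epoch}")
            loss_history.append(epoch_loss)

        results = MapNetworkResults(
            params=params, spec=spec, feature_names=self.feature_names,
            target_mean=y_mean, target_sd=y_sd,
            loss_history=np.asarray(loss_history),
        )
        results.training_metrics = results.evaluate(self.exog, self.endog)
        return results


@dataclass
class MapNetworkResults:
    """A trained MAP network: weights, spec, loss history and metrics."""

    params: list
    spec: NetworkSpec
    feature_names: tuple[str, ...]
    target_mean: float
    target_sd: float
    loss_history: np.ndarray
    training_metrics: FitMetrics | None = None
    validation_metrics: FitMetrics | None = field(default=None)

    def _features_from(self, data) -> np.ndarray:
        if isinstance(data, CalibrationDataset):
            return data.features(self.feature_names)
        if isinstance(data, pd.DataFrame):
            from ..registry import canonical_name

            cols = {}
            for c in data.columns:
                if isinstance(c, str):
                    try:
                        cols[c] = canonical_name(c)
                    except KeyError:
                        pass  # non-compound column, leave untouched
            frame = data.rename(columns=cols) if cols else data
            missing = [f for f in self.feature_names if f not in frame.columns]
            if missing:
                raise SchemaError(f"input lacks feature column(s): {missing}")
            return frame[list(self.feature_names)].to_numpy(dtype=float)
        arr = np.asarray(data, dtype=float)
        if arr.ndim == 1:
            arr = arr[None, :]
        if arr.shape[1] != len(self.feature_names):
            raise SchemaError(
                f"expected {len(self.feature_names)} feature columns, "
                f"got {arr.shape[1]}"
            )
        return arr

    def predict(self, data, *, clamp_nonnegative: bool = False) -> np.ndarray:
        """MAP estimates in mm/yr, one per input sample."""
        X = self._features_from(data)
        out, _, _ = _forward(self.params, X)
        est = out * self.target_sd + self.target_mean
        return np.clip(est, 0.0, None) if clamp_nonnegative else est

    def evaluate(self, data, observed=None) -> FitMetrics:
        """Metrics (mm) against observed MAP."""
        if isinstance(data, CalibrationDataset) and observed is None:
            observed = data.map_mm.to_numpy(dtype=float)
        return evaluate(self.predict(data), observed)

    def summary(self) -> str:
        s = self.spec
        lines = [
            "MAP calibration network",
            "=" * 47,
            f"features:       {', '.join(self.feature_names)}",
            f"architecture:   {len(self.feature_names)} -> "
            + " -> ".join([str(s.neurons)] * s.hidden_layers) + " -> 1 (ReLU)",
            f"optimizer:      Adam lr={s.learning_rate} rho=({s.rho1}, {s.rho2})",
            f"epochs:         {s.epochs} "
            f"(batch={'full' if s.minibatch is None else s.minibatch})",
            f"seed:           {s.seed}",
        ]
        if len(self.loss_history):
            lines.append(f"final MAE loss: {self.loss_history[-1]:.4f} (standardized)")
        if self.training_metrics is not None:
            lines.append(f"training:       {self.training_metrics}")
        if self.validation_metrics is not None:
            lines.append(f"validation:     {self.validation_metrics}")
        return "\n".join(lines)

    # -- portable artifact ------------------------------------------------
    def save(self, path) -> None:
        """Serialize weights + spec + metrics to a JSON artifact."""
        payload = {
            "version": _ARTIFACT_VERSION,
            "spec": self.spec.__dict__,
            "feature_names": list(self.feature_names),
            "target_mean": self.target_mean,
            "target_sd": self.target_sd,
            "loss_history": self.loss_history.tolist(),
            "params": [[w.tolist(), b.tolist()] for w, b in self.params],
            "training_metrics": (None if self.training_metrics is None
                                 else self.training_metrics.__dict__),
            "validation_metrics": (None if self.validation_metrics is None
                                   else self.validation_metrics.__dict__),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "MapNetworkResults":
        payload = json.loads(Path(path).read_text())
        if payload.get("version") != _ARTIFACT_VERSION:
            raise ValueError(f"unsupported artifact version: "
                             f"{payload.get('version')}")
        mk = lambda d: None if d is None else FitMetrics(**d)
        return cls(
            params=[(np.asarray(w), np.asarray(b))
                    for w, b in payload["params"]],
            spec=NetworkSpec(**payload["spec"]),
            feature_names=tuple(payload["feature_names"]),
            target_mean=payload["target_mean"],
            target_sd=payload["target_sd"],
            loss_history=np.asarray(payload["loss_history"]),
            training_metrics=mk(payload["training_metrics"]),
            validation_metrics=mk(payload["validation_metrics"]),
        )


def train_dlnn(training: CalibrationDataset, spec: NetworkSpec | None = None,
               features=DEFAULT_FEATURES,
               validation: CalibrationDataset | None = None
               ) -> MapNetworkResults:
    """Convenience wrapper: build, fit and optionally validate."""
    results = MapNetwork.from_dataset(training, features, spec).fit()
    if validation is not None:
        results.validation_metrics = results.evaluate(validation)
    return results


def predict_map(model: MapNetworkResults, data, *,
                clamp_nonnegative: bool = False) -> np.ndarray:
    """Functional alias of :meth:`MapNetworkResults.predict`."""
    return model.predict(data, clamp_nonnegative=clamp_nonnegative)
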