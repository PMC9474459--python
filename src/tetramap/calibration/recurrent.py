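"""Recurrent baseline models (plain RNN, LSTM, GRU) for MAP calibration.

These baselines consume the feature vector as an ordered scalar sequence
(one compound fraction per time step, registry order) and regress MAP
from the final hidden state through a linear readout.  They exist to
reproduce the overfitting comparison: with small calibration datasets
the recurrent models fit the training set almost perfectly but
generalise worse than the plain feed-forward network.

Cell equations (x_t scalar, h the hidden vector, sigma the logistic
function):

RNN      h_t = tanh(U x_t + W h_{t-1})
LSTM     f_t = sigma(W_fh h_{t-1} + w_fx x_t + b_f)
         i_t = sigma(W_ih h_{t-1} + w_ix x_t + b_i)
         c~_t = tanh(W_ch h_{t-1} + w_cx x_t + b_c)
         C_t = f_t * C_{t-1} + i_t * c~_t
         o_t = sigma(W_oh h_{t-1} + w_ox x_t + b_o)   [standard output
         h_t = o_t * tanh(C_t)                         gate, added]
GRU      r_t = sigma(W_rh h_{t-1} + w_rx x_t)
         z_t = sigma(W_zh h_{t-1} + w_zx x_t)
         h~_t = tanh(W_hh (r_t * h_{t-1}) + w_hx x_t)
         h_t = (1 - z_t) * r_t * h_{t-1} + z_t * h~_t

The GRU state update keeps the reset gate inside the (1 - z) term — a
nonstandard coupling implemented verbatim for fidelity; pass
``standard_gru=True`` for the conventional
``h_t = (1 - z_t) * h_{t-1} + z_t * h~_t``.

Training uses the same Adam/MAE machinery as the feed-forward network,
with targets standardized internally and metrics reported in mm.
Gradients are exact backpropagation through time (verified against
finite differences in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..containers import CalibrationDataset
from ..errors import DivergenceError
from .dataset import DEFAULT_FEATURES
from .metrics import FitMetrics, evaluate
from .network import AdamState, NetworkSpec, adam_step

__all__ = ["RnnParams", "LstmParams", "GruParams", "BaselineSpec",
           "TrainedBaseline", "baseline_cell_forward", "train_baseline"]


def _sigma(x):
    return 1.0 / (1.0 + np.exp(-x))


# --------------------------------------------------------------------------
# parameters


@dataclass
class RnnParams:
    u: np.ndarray          # input weights (H,)
    w: np.ndarray          # recurrent weights (H, H)
    v: np.ndarray          # readout weights (H,)
    c: float = 0.0         # readout bias

    def arrays(self):
        return {"u": self.u, "w": self.w, "v": self.v,
                "c": np.atleast_1d(self.c)}


@dataclass
class LstmParams:
    w_fh: np.ndarray; w_fx: np.ndarray; b_f: np.ndarray
    w_ih: np.ndarray; w_ix: np.ndarray; b_i: np.ndarray
    w_ch: np.ndarray; w_cx: np.ndarray; b_c: np.ndarray
    w_oh: np.ndarray; w_ox: np.ndarray; b_o: np.ndarray
    v: np.ndarray; c: float = 0.0

    def arrays(self):
        d = {k: getattr(self, k) for k in
             ("w_fh", "w_fx", "b_f", "w_ih", "w_ix", "b_i",
              "w_ch", "w_cx", "b_c", "w_oh", "w_ox", "b_o", "v")}
        d["c"] = np.atleast_1d(self.c)
        return d


@dataclass
class GruParams:
    w_rh: np.ndarray; w_rx: np.ndarray
    w_zh: np.ndarray; w_zx: np.ndarray
    w_hh: np.ndarray; w_hx: np.ndarray
    v: np.ndarray; c: float = 0.0

    def arrays(self):
        d = {k: getattr(self, k) for k in
             ("w_rh", "w_rx", "w_zh", "w_zx", "w_hh", "w_hx", "v")}
        d["c"] = np.atleast_1d(self.c)
        return d


def _init_params(kind: str, hidden: int, rng: np.random.Generator):
    s = 1.0 / np.sqrt(hidden)
    vec = lambda: rng.standard_normal(hidden) * s
    mat = lambda: rng.standard_normal((hidden, hidden)) * s
    zero = lambda: np.zeros(hidden)
    if kind == "RNN":
        return RnnParams(u=vec(), w=mat(), v=vec())
    if kind == "LSTM":
        return LstmParams(w_fh=mat(), w_fx=vec(), b_f=zero(),
                          w_ih=mat(), w_ix=vec(), b_i=zero(),
                          w_ch=mat(), w_cx=vec(), b_c=zero(),
                          w_oh=mat(), w_ox=vec(), b_o=zero(), v=vec())
    if kind == "GRU":
        return GruParams(w_rh=mat(), w_rx=vec(), w_zh=mat(), w_zx=vec(),
                         w_hh=mat(), w_hx=vec(), v=vec())
    raise ValueError(f"kind must be RNN, LSTM or GRU, got {kind!r}")


# --------------------------------------------------------------------------
# forward passes (caches kept for backpropagation through time)


@dataclass
class ForwardPass:
    """Hidden trajectory of one forward pass (n samples, T steps)."""

    hidden: np.ndarray              # (n, T, H): h_1 .. h_T
    cell: np.ndarray | None = None  # LSTM cell states C_1 .. C_T
    cache: dict = field(default_factory=dict, repr=False)

    @property
    def final(self) -> np.ndarray:
        return self.hidden[:, -1, :]


def baseline_cell_forward(params, inputs, *, h0=None, c0=None,
                          standard_gru: bool = False) -> ForwardPass:
    """Run a recurrent cell over scalar-per-step inputs.

    Parameters
    ----------
    params : RnnParams | LstmParams | GruParams
    inputs : array (n, T) or (T,)
        One scalar per time step per sample.
    h0, c0 : arrays (n, H), optional
        Initial hidden (and for LSTM, cell) state; default zeros.
    standard_gru : bool
        Use the conventional GRU state update instead of the
        reset-inside-(1-z) form.
    """
    X = np.asarray(inputs, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    n, T = X.shape
    H = len(params.v)
    h = np.zeros((n, H)) if h0 is None else np.asarray(h0, float) * np.ones((n, H))
    hs = np.empty((n, T, H))
    cache: dict = {"x": X, "h0": h.copy()}

    if isinstance(params, RnnParams):
        for t in range(T):
            h = np.tanh(X[:, t, None] * params.u + h @ params.w.T)
            hs[:, t] = h
        return ForwardPass(hidden=hs, cache=cache)

    if isinstance(params, LstmParams):
        C = np.zeros((n, H)) if c0 is None else np.asarray(c0, float) * np.ones((n, H))
        cs = np.empty((n, T, H))
        gates = {k: np.empty((n, T, H)) for k in "fioc"}
        cache["c0"] = C.copy()
        for t in range(T):
            x = X[:, t, None]
            f = _sigma(h @ params.w_fh.T + x * params.w_fx + params.b_f)
            i = _sigma(h @ params.w_ih.T + x * params.w_ix + params.b_i)
            ct = np.tanh(h @ params.w_ch.T + x * params.w_cx + params.b_c)
            o = _sigma(h @ params.w_oh.T + x * params.w_ox + params.b_o)
            C = f * C + i * ct
            h = o * np.tanh(C)
            hs[:, t], cs[:, t] = h, C
            gates["f"][:, t], gates["i"][:, t] = f, i
            gates["o"][:, t], gates["c"][:, t] = o, ct
        cache["gates"] = gates
        return ForwardPass(hidden=hs, cell=cs, cache=cache)

    if isinstance(params, GruParams):
        gates = {k: np.empty((n, T, H)) for k in ("r", "z", "ht")}
        cache["standard"] = standard_gru
        for t in range(T):
            x = X[:, t, None]
            r = _sigma(h @ params.w_rh.T + x * params.w_rx)
            z = _sigma(h @ params.w_zh.T + x * params.w_zx)
            ht = np.tanh((r * h) @ params.w_hh.T + x * params.w_hx)
            h = ((1 - z) * h if standard_gru else (1 - z) * r * h) + z * ht
            hs[:, t] = h
            gates["r"][:, t], gates["z"][:, t], gates["ht"][:, t] = r, z, ht
        cache["gates"] = gates
        return ForwardPass(hidden=hs, cache=cache)

    raise TypeError(f"unsupported params type {type(params).__name__}")


# --------------------------------------------------------------------------
# backpropagation through time


def _prev(hs, h0, t):
    return h0 if t == 0 else hs[:, t - 1]


def _bptt_rnn(p: RnnParams, fp: ForwardPass, dh_final):
    X, h0, hs = fp.cache["x"], fp.cache["h0"], fp.hidden
    g = {k: np.zeros_like(v) for k, v in
         (("u", p.u), ("w", p.w))}
    dh = dh_final
    for t in range(X.shape[1] - 1, -1, -1):
        h = hs[:, t]
        dz = dh * (1.0 - h * h)
        g["u"] += (dz * X[:, t, None]).sum(0)
        g["w"] += dz.T @ _prev(hs, h0, t)
        dh = dz @ p.w
    return g


def _bptt_lstm(p: LstmParams, fp: ForwardPass, dh_final):
    X, h0, C0 = fp.cache["x"], fp.cache["h0"], fp.cache["c0"]
    hs, cs, gt = fp.hidden, fp.cell, fp.cache["gates"]
    names = ("w_fh", "w_fx", "b_f", "w_ih", "w_ix", "b_i",
             "w_ch", "w_cx", "b_c", "w_oh", "w_ox", "b_o")
    g = {k: np.zeros_like(getattr(p, k)) for k in names}
    dh = dh_final
    dC = np.zeros_like(dh)
    for t in range(X.shape[1] - 1, -1, -1):
        x = X[:, t, None]
        hp = _prev(hs, h0, t)
        Cp = C0 if t == 0 else cs[:, t - 1]
        f, i = gt["f"][:, t], gt["i"][:, t]
        o, ct = gt["o"][:, t], gt["c"][:, t]
        tC = np.tanh(cs[:, t])
        do = dh * tC
        dC = dC + dh * o * (1.0 - tC * tC)
        df, di, dct = dC * Cp, dC * ct, dC * i
        dC = dC * f
        dh = np.zeros_like(dh)
        for pre, gate, wh, wx, b, sig in (
                (df, f, "w_fh", "w_fx", "b_f", True),
                (di, i, "w_ih", "w_ix", "b_i", True),
                (dct, ct, "w_ch", "w_cx", "b_c", False),
                (do, o, "w_oh", "w_ox", "b_o", True)):
            dz = pre * (gate * (1 - gate) if sig else (1 - gate * gate))
            g[wh] += dz.T @ hp
            g[wx] += (dz * x).sum(0)
            g[b] += dz.sum(0)
            dh += dz @ getattr(p, wh)
    return g


def _bptt_gru(p: GruParams, fp: ForwardPass, dh_final):
    X, h0, gt = fp.cache["x"], fp.cache["h0"], fp.cache["gates"]
    hs = fp.hidden
    standard = fp.cache["standard"]
    names = ("w_rh", "w_rx", "w_zh", "w_zx", "w_hh", "w_hx")
    g = {k: np.zeros_like(getattr(p, k)) for k in names}
    dh = dh_final
    for t in range(X.shape[1] - 1, -1, -1):
        x = X[:, t, None]
        hp = _prev(hs, h0, t)
        r, z, ht = gt["r"][:, t], gt["z"][:, t], gt["ht"][:, t]
        if standard:
            dz_gate = dh * (ht - hp)
            dhp = dh * (1 - z)
            dr = np.zeros_like(r)
        else:
            dz_gate = dh * (ht - r * hp)
            dhp = dh * (1 - z) * r
            dr = dh * (1 - z) * hp
        dht = dh * z
        dpre_h = dht * (1 - ht * ht)
        g["w_hh"] += dpre_h.T @ (r * hp)
        g["w_hx"] += (dpre_h * x).sum(0)
        drh = dpre_h @ p.w_hh
        dr = dr + drh * hp
        dhp = dhp + drh * r
        dpre_r = dr * r * (1 - r)
        g["w_rh"] += dpre_r.T @ hp
        g["w_rx"] += (dpre_r * x).sum(0)
        dhp = dhp + dpre_r @ p.w_rh
        dpre_z = dz_gate * z * (1 - z)
        g["w_zh"] += dpre_z.T @ hp
        g["w_zx"] += (dpre_z * x).sum(0)
        dhp = dhp + dpre_z @ p.w_zh
        dh = dhp
    return g


def gradients(params, inputs, dloss_dy, *, standard_gru: bool = False,
              forward: ForwardPass | None = None) -> dict[str, np.ndarray]:
    """Exact loss gradients for every parameter array.

    ``dloss_dy`` is the per-sample derivative of the loss w.r.t. the
    scalar readout ``y = v . h_T + c``.
    """
    fp = forward or baseline_cell_forward(params, inputs,
                                          standard_gru=standard_gru)
    dldy = np.asarray(dloss_dy, dtype=float).ravel()
    hT = fp.final
    g = {"v": hT.T @ dldy, "c": np.atleast_1d(dldy.sum())}
    dh_final = dldy[:, None] * params.v
    if isinstance(params, RnnParams):
        g.update(_bptt_rnn(params, fp, dh_final))
    elif isinstance(params, LstmParams):
        g.update(_bptt_lstm(params, fp, dh_final))
    else:
        g.update(_bptt_gru(params, fp, dh_final))
    return g


# --------------------------------------------------------------------------
# training


@dataclass(frozen=True)
class BaselineSpec:
    """Hyperparameters for a recurrent baseline."""

    kind: str = "RNN"               # RNN | LSTM | GRU
    hidden: int = 32
    epochs: int = 1500
    learning_rate: float = 0.001
    rho1: float = 0.9
    rho2: float = 0.999
    epsilon: float = 1e-8
    seed: int = 0
    standard_gru: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("RNN", "LSTM", "GRU"):
            raise ValueError("kind must be RNN, LSTM or GRU")
        if self.hidden < 1 or self.epochs < 0 or self.learning_rate <= 0:
            raise ValueError("hidden >= 1, epochs >= 0 and positive "
                             "learning rate required")

    def adam(self) -> NetworkSpec:
        return NetworkSpec(learning_rate=self.learning_rate, rho1=self.rho1,
                           rho2=self.rho2, epsilon=self.epsilon,
                           epochs=max(self.epochs, 0))


@dataclass
class TrainedBaseline:
    """A trained recurrent baseline with its metrics."""

    params: object
    spec: BaselineSpec
    feature_names: tuple[str, ...]
    target_mean: float
    target_sd: float
    loss_history: np.ndarray
    training_metrics: FitMetrics | None = None
    validation_metrics: FitMetrics | None = None

    def predict(self, data) -> np.ndarray:
        X = (data.features(self.feature_names)
             if isinstance(data, CalibrationDataset)
             else np.asarray(data, dtype=float))
        fp = baseline_cell_forward(self.params, X,
                                   standard_gru=self.spec.standard_gru)
        y = fp.final @ self.params.v + self.params.c
        return y * self.target_sd + self.target_mean

    def evaluate(self, data, observed=None) -> FitMetrics:
        if isinstance(data, CalibrationDataset) and observed is None:
            observed = data.map_mm.to_numpy(dtype=float)
        return evaluate(self.predict(data), observed)


def train_baseline(kind: str, training: CalibrationDataset,
                   spec: BaselineSpec | None = None, seed: int | None = None,
                   *, features=DEFAULT_FEATURES,
                   validation: CalibrationDataset | None = None
                   ) -> TrainedBaseline:
    """Train a recurrent baseline with full-batch Adam on MAE.

    The composition is consumed as a scalar sequence in the order of
    ``features``; the target is standardized internally and metrics are
    reported in mm.  Deterministic given the seed.
    """
    spec = spec or BaselineSpec(kind=kind)
    if spec.kind != kind:
        spec = BaselineSpec(**{**spec.__dict__, "kind": kind})
    if seed is not None and seed != spec.seed:
        spec = BaselineSpec(**{**spec.__dict__, "seed": seed})
    rng = np.random.default_rng(spec.seed)
    params = _init_params(spec.kind, spec.hidden, rng)

    X = training.features(features)
    y_raw = training.map_mm.to_numpy(dtype=float)
    y_mean, y_sd = float(y_raw.mean()), float(y_raw.std()) or 1.0
    y = (y_raw - y_mean) / y_sd
    n = len(y)

    arrays = params.arrays()
    states = {k: AdamState() for k in arrays}
    adam = spec.adam()
    history = []
    for epoch in range(spec.epochs):
        fp = baseline_cell_forward(params, X, standard_gru=spec.standard_gru)
        out = fp.final @ params.v + params.c
        resid = out - y
        loss = float(np.abs(resid).mean())
        if not np.isfinite(loss):
            raise DivergenceError(f"non-finite loss at epoch {epoch}")
        history.append(loss)
        g = gradients(params, X, np.sign(resid) / n,
                      standard_gru=spec.standard_gru, forward=fp)
        for name in arrays:
            states[name], dw = adam_step(states[name], g[name], adam)
            if name == "c":
                params.c = float(params.c + dw[0])
            else:
                setattr(params, name, getattr(params, name) + dw)

    result = TrainedBaseline(
        params=params, spec=spec, feature_names=tuple(features),
        target_mean=y_mean, target_sd=y_sd,
        loss_history=np.asarray(history),
    )
    result.training_metrics = result.evaluate(training)
    if validation is not None:
        result.validation_metrics = result.evaluate(validation)
    return result
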