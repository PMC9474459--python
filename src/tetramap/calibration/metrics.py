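"""Fit metrics shared by every calibration model.

R-squared is reported as the squared Pearson correlation between
predictions and observations (the squared multiple-correlation form),
which coincides with the usual coefficient of determination for
least-squares linear fits but remains well defined for the nonlinear
models.  Zero variance in either vector flags R-squared as undefined
(NaN) rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FitMetrics", "mae_loss", "evaluate"]


@dataclass(frozen=True)
class FitMetrics:
    """Goodness-of-fit summary in target units (mm/yr for MAP models)."""

    r2: float       # squared Pearson correlation; NaN when undefined
    rmse: float
    mae: float
    n: int

    def __str__(self) -> str:
        return (f"R2={self.r2:.3f} RMSE={self.rmse:.1f} "
                f"MAE={self.mae:.1f} (n={self.n})")


def _pair(targets, predictions) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(targets, dtype=float).ravel()
    y = np.asarray(predictions, dtype=float).ravel()
    if t.shape != y.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {y.shape}")
    if t.size == 0:
        raise ValueError("empty input")
    return t, y


def mae_loss(targets, predictions) -> float:
    """Mean absolute error (1/N) sum |T - Y|."""
    t, y = _pair(targets, predictions)
    return float(np.mean(np.abs(t - y)))


def evaluate(predictions, observations) -> FitMetrics:
    """R-squared, RMSE and MAE of predictions against observations."""
    obs, pred = _pair(observations, predictions)
    resid = obs - pred
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    mae = float(np.mean(np.abs(resid)))
    if np.std(obs) == 0:
        r2 = float("nan")            # undefined: nothing to explain
    elif np.std(pred) == 0:
        r2 = 0.0                     # constant predictor explains nothing
    else:
        r2 = float(np.corrcoef(pred, obs)[0, 1] ** 2)
    return FitMetrics(r2=r2, rmse=rmse, mae=mae, n=int(obs.size))
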