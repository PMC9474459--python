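"""Grid search and feature-ablation protocol for the MAP network.

``grid_search`` trains one network per (epochs, neurons) grid cell on a
fixed training/validation split and selects the cell with the highest
validation R-squared, breaking ties by lower validation RMSE and then
by fewer neurons.  ``ablate_features`` retrains with each candidate
compound removed and reports the change in validation skill; a large
negative delta-R-squared marks a compound the model depends on.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ..containers import CalibrationDataset
from .dataset import DEFAULT_FEATURES
from .network import MapNetworkResults, NetworkSpec, train_dlnn

__all__ = ["GridSearchResult", "grid_search", "ablate_features",
           "DEFAULT_EPOCH_GRID", "DEFAULT_NEURON_GRID"]

DEFAULT_EPOCH_GRID: tuple[int, ...] = tuple(range(1000, 1501, 100))
DEFAULT_NEURON_GRID: tuple[int, ...] = tuple(range(160, 261, 20))


@dataclass
class GridSearchResult:
    """Best specification plus the full score table of a grid search."""

    best_spec: NetworkSpec
    best_results: MapNetworkResults
    scores: pd.DataFrame   # epochs, neurons, train/val R2 and RMSE

    def summary(self) -> str:
        lines = ["Grid search over (epochs, neurons)", "=" * 48,
                 self.scores.to_string(index=False,
                                       float_format=lambda v: f"{v:.4f}"),
                 "-" * 48,
                 f"selected: epochs={self.best_spec.epochs} "
                 f"neurons={self.best_spec.neurons}"]
        return "\n".join(lines)


def grid_search(training: CalibrationDataset,
                validation: CalibrationDataset,
                epoch_grid=DEFAULT_EPOCH_GRID,
                neuron_grid=DEFAULT_NEURON_GRID,
                seed: int = 0, *, features=DEFAULT_FEATURES,
                spec: NetworkSpec | None = None) -> GridSearchResult:
    """Train one network per grid cell and pick the best on validation.

    All cells share the same split, feature set and seed; only epochs
    and neuron count vary.  ``spec`` supplies the non-grid
    hyperparameters (learning rate, depth, ...).
    """
    epoch_grid = tuple(int(e) for e in epoch_grid)
    neuron_grid = tuple(int(k) for k in neuron_grid)
    if not epoch_grid or not neuron_grid:
        raise ValueError("epoch and neuron grids must be non-empty")
    base = spec or NetworkSpec()

    rows, fits = [], {}
    for epochs in epoch_grid:
        for neurons in neuron_grid:
            cell = NetworkSpec(**{**base.__dict__, "epochs": epochs,
                                  "neurons": neurons, "seed": seed})
            res = train_dlnn(training, cell, features=features,
                             validation=validation)
            fits[(epochs, neurons)] = res
            tm, vm = res.training_metrics, res.validation_metrics
            rows.append({"epochs": epochs, "neurons": neurons,
                         "train_r2": tm.r2, "train_rmse": tm.rmse,
                         "val_r2": vm.r2, "val_rmse": vm.rmse})
    scores = pd.DataFrame(rows)

    # max val R2, ties -> lower val RMSE -> fewer neurons -> fewer epochs
    ranked = scores.sort_values(
        ["val_r2", "val_rmse", "neurons", "epochs"],
        ascending=[False, True, True, True], kind="mergesort")
    top = ranked.iloc[0]
    key = (int(top["epochs"]), int(top["neurons"]))
    return GridSearchResult(best_spec=fits[key].spec,
                            best_results=fits[key], scores=scores)


def ablate_features(training: CalibrationDataset,
                    validation: CalibrationDataset,
                    base_features=DEFAULT_FEATURES,
                    spec: NetworkSpec | None = None,
                    candidates=None) -> pd.DataFrame:
    """Retrain with each candidate compound removed; report skill deltas.

    Candidates default to every base feature except Ia (removing the
    dominant tetramethylated fraction is not part of the protocol); the
    default base set therefore yields the seven-row table
    {Ic, IIa', IIb', IIc', IIIa', IIIb', IIIc'}.  Negative
    ``delta_r2`` means the model got worse without the compound.
    """
    base_features = tuple(base_features)
    if not base_features:
        raise ValueError("base feature set is empty")
    if candidates is None:
        candidates = tuple(f for f in base_features if f != "Ia")
    missing = [c for c in candidates if c not in base_features]
    if missing:
        raise ValueError(f"candidates not in base features: {missing}")
    if len(base_features) == 1:
        raise ValueError("cannot ablate the only remaining feature")

    spec = spec or NetworkSpec()
    full = train_dlnn(training, spec, features=base_features,
                      validation=validation)
    vr2, vrmse = (full.validation_metrics.r2, full.validation_metrics.rmse)

    rows = []
    for comp in candidates:
        reduced = tuple(f for f in base_features if f != comp)
        res = train_dlnn(training, spec, features=reduced,
                         validation=validation)
        vm = res.validation_metrics
        rows.append({"removed": comp, "val_r2": vm.r2,
                     "val_rmse": vm.rmse, "delta_r2": vm.r2 - vr2,
                     "delta_rmse": vm.rmse - vrmse})
    table = pd.DataFrame(rows)
    table.attrs["full_val_r2"] = vr2
    table.attrs["full_val_rmse"] = vrmse
    return table.sort_values("delta_r2", kind="mergesort",
                             ignore_index=True)
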