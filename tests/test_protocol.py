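"""Split, grid-search and ablation protocol."""

import numpy as np
import pandas as pd
import pytest

from tetramap.calibration import (NetworkSpec, grid_search, ablate_features,
                                  split_dataset)
from tetramap.containers import CalibrationDataset
from tetramap.registry import COMPOUND_NAMES
from tetramap.synthetic import GeneratorConfig, generate_calibration_dataset

FAST = NetworkSpec(hidden_layers=2, neurons=16, epochs=80)


# --------------------------------------------------------------------------
# split


def test_split_sizes_533_179():
    ds, _ = generate_calibration_dataset(GeneratorConfig(n=712, seed=30))
    training, validation = split_dataset(ds, 179.0 / 712.0, seed=0)
    assert len(training) == 533
    assert len(validation) == 179


def test_split_disjoint_exhaustive_deterministic():
    ds, _ = generate_calibration_dataset(GeneratorConfig(n=50, seed=31))
    t1, v1 = split_dataset(ds, 0.5, seed=4)
    t2, v2 = split_dataset(ds, 0.5, seed=4)
    assert len(t1) == 25 and len(v1) == 25
    i_t = set(t1.abundances.index)
    i_v = set(v1.abundances.index)
    assert i_t.isdisjoint(i_v)
    assert i_t | i_v == set(ds.abundances.index)
    assert set(t2.abundances.index) == i_t


def test_split_small_n_rejected():
    frame = pd.DataFrame([np.full(15, 1 / 15)], columns=list(COMPOUND_NAMES))
    ds = CalibrationDataset(abundances=frame,
                            map_mm=pd.Series([500.0], name="MAP_mm"))
    from tetramap.errors import InsufficientDataError

    with pytest.raises(InsufficientDataError):
        split_dataset(ds, 0.5, seed=0)


# --------------------------------------------------------------------------
# grid search


@pytest.fixture(scope="module")
def split_small():
    ds, _ = generate_calibration_dataset(GeneratorConfig(n=140, seed=32))
    return ds.split(0.25, seed=1)


def test_single_cell_grid_returns_that_cell(split_small):
    training, validation = split_small
    gs = grid_search(training, validation, epoch_grid=[60],
                     neuron_grid=[12], seed=0, spec=FAST)
    assert gs.best_spec.epochs == 60
    assert gs.best_spec.neurons == 12
    assert len(gs.scores) == 1


def test_grid_cells_enumerated(split_small):
    training, validation = split_small
    gs = grid_search(training, validation, epoch_grid=[40, 60],
                     neuron_grid=[8, 12], seed=0, spec=FAST)
    assert len(gs.scores) == 4
    assert set(zip(gs.scores["epochs"], gs.scores["neurons"])) == \
        {(40, 8), (40, 12), (60, 8), (60, 12)}


def test_grid_search_deterministic(split_small):
    training, validation = split_small
    kwargs = dict(epoch_grid=[40, 60], neuron_grid=[8, 12], seed=0,
                  spec=FAST)
    g1 = grid_search(training, validation, **kwargs)
    g2 = grid_search(training, validation, **kwargs)
    assert (g1.best_spec.epochs, g1.best_spec.neurons) == \
        (g2.best_spec.epochs, g2.best_spec.neurons)
    assert np.array_equal(g1.scores.to_numpy(), g2.scores.to_numpy())


def test_grid_search_selects_max_val_r2(split_small):
    training, validation = split_small
    gs = grid_search(training, validation, epoch_grid=[40, 60],
                     neuron_grid=[8, 12], seed=0, spec=FAST)
    best_row = gs.scores.loc[gs.scores["val_r2"].idxmax()]
    assert gs.best_spec.epochs == int(best_row["epochs"])
    assert gs.best_spec.neurons == int(best_row["neurons"])


def test_empty_grid_rejected(split_small):
    training, validation = split_small
    with pytest.raises(ValueError):
        grid_search(training, validation, epoch_grid=[], neuron_grid=[8])


# --------------------------------------------------------------------------
# ablation


def test_ablation_has_seven_rows(split_small):
    training, validation = split_small
    table = ablate_features(training, validation, spec=FAST)
    assert len(table) == 7
    assert set(table["removed"]) == set(f for f in
                                        ("Ic", "IIa′", "IIb′", "IIc′",
                                         "IIIa′", "IIIb′", "IIIc′"))
    assert {"val_r2", "val_rmse", "delta_r2", "delta_rmse"} <= \
        set(table.columns)


def test_ablation_rejects_foreign_candidate(split_small):
    training, validation = split_small
    with pytest.raises(ValueError):
        ablate_features(training, validation, candidates=["IIb"], spec=FAST)


def test_ablating_null_feature_harmless():
    # target depends only on Ia; removing a compound with zero true
    # effect must barely move validation skill, removing Ia must hurt most
    rng = np.random.default_rng(33)
    n = 300
    ia = rng.uniform(0.0, 0.8, n)
    rest = rng.dirichlet(np.ones(14), size=n) * (1.0 - ia)[:, None]
    frame = pd.DataFrame(np.column_stack([ia, rest]),
                         columns=list(COMPOUND_NAMES))
    y = 2000.0 * frame["Ia"] + 400.0 + rng.normal(0, 30.0, n)
    ds = CalibrationDataset(abundances=frame,
                            map_mm=pd.Series(y, name="MAP_mm"))
    training, validation = ds.split(0.25, seed=2)
    spec = NetworkSpec(hidden_layers=2, neurons=24, epochs=250)
    table = ablate_features(training, validation, spec=spec,
                            candidates=("Ia", "IIb′"))
    by = table.set_index("removed")
    assert by.loc["Ia", "delta_r2"] < -0.2            # dominant feature
    assert abs(by.loc["IIb′", "delta_r2"]) < 0.1      # null feature
    assert by["delta_r2"].idxmin() == "Ia"
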