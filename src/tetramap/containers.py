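"""In-memory containers for calibration compilations and downcore profiles."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abundance import validate_abundances
from .errors import InsufficientDataError, OrderingError, ValidationError
from .registry import COMPOUND_NAMES


@dataclass
class CalibrationDataset:
    """Surface-soil calibration rows: composition plus observed climate.

    Attributes
    ----------
    abundances : pandas.DataFrame
        One row per site, the 15 compound columns in registry order,
        each row on the unit simplex.
    map_mm : pandas.Series
        Observed mean annual precipitation (mm/yr), aligned with
        ``abundances``.
    map_alt_mm, mat_c, ph : pandas.Series, optional
        Alternate gridded-climate MAP, mean annual temperature (degC) and
        soil pH where available.
    source : pandas.Series, optional
        Provenance label per row (publication, laboratory).
    """

    abundances: pd.DataFrame
    map_mm: pd.Series
    map_alt_mm: pd.Series | None = None
    mat_c: pd.Series | None = None
    ph: pd.Series | None = None
    source: pd.Series | None = None

    def __post_init__(self) -> None:
        validate_abundances(self.abundances)
        if (np.asarray(self.map_mm, dtype=float) < 0).any():
            raise ValidationError("MAP must be non-negative")
        if len(self.map_mm) != len(self.abundances):
            raise ValidationError("abundances and MAP lengths differ")

    def __len__(self) -> int:
        return len(self.abundances)

    @property
    def n(self) -> int:
        return len(self)

    def features(self, names) -> np.ndarray:
        """Feature matrix (n, k) for the requested compound columns."""
        from .registry import canonical_names

        return self.abundances[canonical_names(names)].to_numpy(dtype=float)

    def subset(self, index) -> "CalibrationDataset":
        """Row subset by positional index array."""
        take = lambda s: None if s is None else s.iloc[index]
        return CalibrationDataset(
            abundances=self.abundances.iloc[index],
            map_mm=self.map_mm.iloc[index],
            map_alt_mm=take(self.map_alt_mm),
            mat_c=take(self.mat_c),
            ph=take(self.ph),
            source=take(self.source),
        )

    def split(self, validation_fraction: float, seed: int
              ) -> tuple["CalibrationDataset", "CalibrationDataset"]:
        """Disjoint, exhaustive uniformly-random training/validation split.

        With ``n`` rows the validation set receives
        ``round(n * validation_fraction)`` rows, so the achieved size
        differs from the requested one by less than 1.
        """
        if not 0 < validation_fraction < 1:
            raise ValueError("validation_fraction must be in (0, 1)")
        n = len(self)
        n_val = int(round(n * validation_fraction))
        if n < 2 or n_val == 0 or n_val == n:
            raise InsufficientDataError(
                f"cannot split n={n} with fraction {validation_fraction}"
            )
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        return self.subset(np.sort(perm[n_val:])), self.subset(np.sort(perm[:n_val]))

    def to_frame(self) -> pd.DataFrame:
        """Flat table: compounds, MAP and any optional columns."""
        out = self.abundances.copy()
        out["MAP_mm"] = self.map_mm
        for name, col in (("MAP_alt_mm", self.map_alt_mm),
                          ("MAT_C", self.mat_c), ("pH", self.ph),
                          ("source", self.source)):
            if col is not None:
                out[name] = col
        return out


#: optional per-depth columns a profile may carry
PROFILE_OPTIONAL = ("susceptibility", "mean_grain_size_um")


@dataclass
class DowncoreProfile:
    """Depth-ordered downcore samples.

    ``table`` must contain a strictly increasing ``depth_m`` column and may
    carry magnetic susceptibility, mean grain size, the 15 brGDGT columns,
    n-alkane homolog columns (``C23`` ... ``C34``) and, once an age model
    has been applied, an ``age_ka`` column.
    """

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if "depth_m" not in self.table.columns:
            raise OrderingError("profile requires a depth_m column")
        depth = self.table["depth_m"].to_numpy(dtype=float)
        if len(depth) and not (np.diff(depth) > 0).all():
            raise OrderingError("depth_m must be strictly increasing")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def depth_m(self) -> np.ndarray:
        return self.table["depth_m"].to_numpy(dtype=float)

    def has_compounds(self) -> bool:
        return all(c in self.table.columns for c in COMPOUND_NAMES)

    def abundances(self) -> pd.DataFrame:
        """The 15 compound columns in registry order."""
        return self.table[list(COMPOUND_NAMES)]

    def with_ages(self, ages_ka: np.ndarray) -> "DowncoreProfile":
        out = self.table.copy()
        out["age_ka"] = np.asarray(ages_ka, dtype=float)
        return DowncoreProfile(out)
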