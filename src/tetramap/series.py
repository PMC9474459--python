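"""Uniformly gridded time series container."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GridMismatchError, InsufficientDataError, OrderingError


@dataclass(frozen=True)
class GriddedSeries:
    """Values on a uniform age grid.

    Attributes
    ----------
    start_ka : float
        Age of the first sample (ka).
    step_ka : float
        Grid spacing (ka), > 0.
    values : numpy.ndarray
        Finite values, one per grid node.
    """

    start_ka: float
    step_ka: float
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values",
                           np.asarray(self.values, dtype=float))
        if self.step_ka <= 0:
            raise ValueError("step_ka must be > 0")
        if not np.isfinite(self.values).all():
            raise ValueError("values must be finite")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def ages_ka(self) -> np.ndarray:
        return self.start_ka + self.step_ka * np.arange(len(self.values))

    def same_grid(self, other: "GriddedSeries", rtol: float = 1e-9) -> bool:
        return (len(self) == len(other)
                and abs(self.start_ka - other.start_ka) <= rtol * max(1.0, abs(self.start_ka))
                and abs(self.step_ka - other.step_ka) <= rtol * self.step_ka)

    def require_same_grid(self, other: "GriddedSeries") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                "series are not on the same uniform age grid; "
                "resample both with resample_to_age_grid first"
            )

    @classmethod
    def from_samples(cls, ages_ka, values, step_ka: float = 1.0
                     ) -> "GriddedSeries":
        """Linear interpolation of irregular samples onto a uniform grid.

        The grid spans only the sampled overlap: from the smallest grid
        multiple >= min(age) to the largest <= max(age).
        """
        ages = np.asarray(ages_ka, dtype=float)
        vals = np.asarray(values, dtype=float)
        if ages.size < 2:
            raise InsufficientDataError("need at least two samples to grid")
        if not (np.diff(ages) > 0).all():
            raise OrderingError("ages must be strictly increasing")
        start = np.ceil(ages[0] / step_ka - 1e-12) * step_ka
        stop = np.floor(ages[-1] / step_ka + 1e-12) * step_ka
        n = int(round((stop - start) / step_ka)) + 1
        grid = start + step_ka * np.arange(n)
        return cls(start_ka=float(start), step_ka=float(step_ka),
                   values=np.interp(grid, ages, vals))
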