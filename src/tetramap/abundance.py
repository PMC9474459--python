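"""Peak areas, fractional abundances and internal-standard quantification.

Fractional abundances are defined over all 15 brGDGTs: each compound's
fraction is its integrated peak area divided by the summed area of the 15
compounds, so a sample's abundance vector lives on the simplex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptySampleError, MissingStandardError, ValidationError
from .registry import COMPOUND_NAMES

__all__ = [
    "PeakAreaRecord",
    "fractional_abundances",
    "validate_abundances",
    "quantify_compound",
    "C46_STANDARD_MICROGRAMS",
]

# Default internal-standard amount: 10 ul of a 0.001157 ug/ul C46 GTGT
# solution spiked into each polar fraction.
C46_STANDARD_MICROGRAMS = 10.0 * 0.001157

#: tolerance on the simplex-sum invariant
SUM_ATOL = 1e-9


@dataclass
class PeakAreaRecord:
    """Integrated peak areas for one sample.

    Parameters
    ----------
    sample_id : str
        Free-text sample identifier.
    areas : mapping
        Per-compound peak area in arbitrary (detector) units; keys are
        compound names (prime or ASCII-apostrophe spelling).
    depth_m : float, optional
        Sample depth in metres for downcore material.
    standard_area : float, optional
        Peak area of the C46 internal standard.
    standard_micrograms : float
        Amount of internal standard added, in micrograms.
    """

    sample_id: str
    areas: dict[str, float]
    depth_m: float | None = None
    standard_area: float | None = None
    standard_micrograms: float = C46_STANDARD_MICROGRAMS
    _vector: pd.Series = field(init=False, repr=False)

    def __post_init__(self) -> None:
        from .registry import canonical_name

        vec = pd.Series(0.0, index=list(COMPOUND_NAMES))
        for name, area in self.areas.items():
            area = float(area)
            if not np.isfinite(area) or area < 0:
                raise ValidationError(
                    f"peak area for {name!r} must be finite and >= 0, got {area}"
                )
            vec[canonical_name(name)] = area
        self._vector = vec

    @property
    def area_vector(self) -> pd.Series:
        """Areas in registry order (missing compounds as 0)."""
        return self._vector.copy()


def _as_frame(values) -> tuple[pd.DataFrame, bool]:
    """Coerce a record/Series/DataFrame of compound values to a DataFrame."""
    if isinstance(values, PeakAreaRecord):
        return values.area_vector.to_frame().T, True
    if isinstance(values, pd.Series):
        return values.to_frame().T, True
    if isinstance(values, pd.DataFrame):
        return values, False
    raise TypeError(f"unsupported input type: {type(values).__name__}")


def fractional_abundances(values):
    """Normalize peak areas to fractional abundances summing to 1.

    Parameters
    ----------
    values : PeakAreaRecord, pandas.Series or pandas.DataFrame
        Peak areas (or any non-negative abundances) with the 15 compounds
        as index/columns.  A DataFrame is treated as one sample per row.

    Returns
    -------
    pandas.Series or pandas.DataFrame
        Same shape as the input, each sample rescaled to unit sum, columns
        in registry order.

    Raises
    ------
    EmptySampleError
        If a sample's total area is zero.
    ValidationError
        If any area is negative or non-finite.
    """
    frame, squeeze = _as_frame(values)
    from .registry import canonical_names

    frame = frame.copy()
    frame.columns = canonical_names(frame.columns)
    missing = [c for c in COMPOUND_NAMES if c not in frame.columns]
    if missing:
        raise ValidationError(f"missing compound columns: {missing}")
    frame = frame[list(COMPOUND_NAMES)].astype(float)

    arr = frame.to_numpy()
    if not np.isfinite(arr).all() or (arr < 0).any():
        raise ValidationError("peak areas must be finite and non-negative")
    totals = arr.sum(axis=1)
    empty = np.flatnonzero(totals <= 0)
    if empty.size:
        raise EmptySampleError(
            f"empty sample(s) with all-zero areas at row(s) {empty.tolist()}"
        )
    out = pd.DataFrame(arr / totals[:, None], index=frame.index,
                       columns=frame.columns)
    return out.iloc[0] if squeeze else out


def validate_abundances(fa, atol: float = SUM_ATOL) -> None:
    """Check the fractional-abundance invariants.

    Each value must lie in [0, 1] and each sample must sum to 1 within
    ``atol``.  Raises :class:`ValidationError` on violation.
    """
    frame, _ = _as_frame(fa)
    arr = frame[list(COMPOUND_NAMES)].to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise ValidationError("abundances must be finite")
    if (arr < 0).any() or (arr > 1 + atol).any():
        raise ValidationError("abundances must lie in [0, 1]")
    sums = arr.sum(axis=1)
    bad = np.flatnonzero(np.abs(sums - 1.0) > atol)
    if bad.size:
        raise ValidationError(
            f"abundances must sum to 1 within {atol}; "
            f"row(s) {bad.tolist()} sum to {sums[bad].tolist()}"
        )


def quantify_compound(record: PeakAreaRecord, compound: str) -> float:
    """Absolute amount of one compound in micrograms.

    Uses the single-point internal-standard response:
    ``mass = area(compound) / area(standard) * standard_micrograms``.

    Raises
    ------
    MissingStandardError
        If the record has no internal-standard area (or it is zero).
    """
    from .registry import canonical_name

    if record.standard_area is None or record.standard_area <= 0:
        raise MissingStandardError(
            f"sample {record.sample_id!r} has no internal standard"
        )
    area = record.area_vector[canonical_name(compound)]
    return float(area) / float(record.standard_area) * record.standard_micrograms
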