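"""Readers and writers for the delimited text tables the package consumes.

All tables are comma- or tab-separated text with a header row.  Column
naming is documented in ``io_schema.md`` shipped alongside this module;
compound columns accept both prime-mark and ASCII-apostrophe spellings
(``IIa′`` / ``IIa'``).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CalibrationDataset, DowncoreProfile
from .errors import SchemaError, ValidationError
from .registry import COMPOUND_NAMES, canonical_name

__all__ = [
    "read_calibration_table",
    "write_calibration_table",
    "read_abundance_table",
    "read_profile_table",
    "write_profile_table",
    "read_control_points",
    "read_series",
    "write_table",
]

#: pre-normalized rows are accepted when their sum is within this band of 1
RENORM_TOL = 0.02

_MAP_ALIASES = ("MAP_mm", "MAP", "map_mm")
_OPTIONAL_ALIASES = {
    "MAP_alt_mm": ("MAP_alt_mm", "MAP_alt", "MAP_terra"),
    "MAT_C": ("MAT_C", "MAT"),
    "pH": ("pH", "ph"),
    "source": ("source", "source_doi", "reference"),
}


def _read(path) -> pd.DataFrame:
    """Read a delimited file, sniffing comma vs. tab."""
    try:
        return pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:  # malformed file
        raise SchemaError(f"{path}: cannot parse table ({exc})") from exc


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def _numeric(frame: pd.DataFrame, columns, path) -> pd.DataFrame:
    """Coerce columns to float, reporting the first offending cell."""
    out = frame.copy()
    for col in columns:
        coerced = pd.to_numeric(out[col], errors="coerce")
        bad = coerced.isna() & out[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(
                f"{path}: non-numeric value {out[col].iloc[row]!r} "
                f"in column {col!r}, data row {row}"
            )
        out[col] = coerced
    return out


def _compound_columns(frame: pd.DataFrame, path, missing_as_zero: bool
                      ) -> pd.DataFrame:
    """Map header spellings to canonical compound names and extract them."""
    rename = {}
    for col in frame.columns:
        try:
            rename[col] = canonical_name(str(col))
        except KeyError:
            continue
    frame = frame.rename(columns=rename)
    missing = [c for c in COMPOUND_NAMES if c not in frame.columns]
    if missing and not missing_as_zero:
        raise SchemaError(f"{path}: missing compound column(s): {missing}")
    for c in missing:
        frame[c] = 0.0
    return frame


def read_abundance_table(path, *, normalize: bool = False,
                         missing_as_zero: bool = False) -> pd.DataFrame:
    """Read per-sample compound values (areas or fractions).

    Returns a DataFrame with the 15 canonical compound columns (plus any
    extra columns such as ``sample_id`` or ``depth_m`` untouched).  With
    ``normalize=True`` each row is rescaled to unit sum, so peak-area
    tables become fractional abundances.
    """
    frame = _compound_columns(_read(path), path, missing_as_zero)
    frame = _numeric(frame, list(COMPOUND_NAMES), path)
    if normalize:
        from .abundance import fractional_abundances

        frame[list(COMPOUND_NAMES)] = fractional_abundances(
            frame[list(COMPOUND_NAMES)]
        ).to_numpy()
    return frame


def read_calibration_table(path, *, renormalize: bool = False,
                           missing_as_zero: bool = False) -> CalibrationDataset:
    """Read a surface-soil calibration compilation.

    The header must name the 15 compounds and a MAP column (``MAP_mm`` or
    ``MAP``).  Rows whose abundance sum deviates from 1 are rejected with
    their row numbers; with ``renormalize=True`` rows within +/-0.02 of 1
    are rescaled instead.
    """
    frame = _compound_columns(_read(path), path, missing_as_zero)
    map_col = next((c for c in _MAP_ALIASES if c in frame.columns), None)
    if map_col is None:
        raise SchemaError(f"{path}: no MAP column (expected one of {_MAP_ALIASES})")
    frame = _numeric(frame, list(COMPOUND_NAMES) + [map_col], path)

    comp = frame[list(COMPOUND_NAMES)].to_numpy(dtype=float)
    sums = comp.sum(axis=1)
    if renormalize:
        bad = np.flatnonzero(np.abs(sums - 1.0) > RENORM_TOL)
    else:
        bad = np.flatnonzero(np.abs(sums - 1.0) > 1e-9)
    if bad.size:
        raise ValidationError(
            f"{path}: abundance rows not summing to 1"
            f"{' within +/-0.02' if renormalize else ''}: "
            f"data row(s) {bad.tolist()} (sums {np.round(sums[bad], 4).tolist()})"
        )
    if renormalize:
        comp = comp / sums[:, None]

    kwargs = {}
    for field_name, aliases in _OPTIONAL_ALIASES.items():
        col = next((c for c in aliases if c in frame.columns), None)
        if col is not None:
            series = frame[col]
            if field_name != "source":
                series = _numeric(frame, [col], path)[col]
            kwargs[{"MAP_alt_mm": "map_alt_mm", "MAT_C": "mat_c",
                    "pH": "ph", "source": "source"}[field_name]] = series
    return CalibrationDataset(
        abundances=pd.DataFrame(comp, columns=list(COMPOUND_NAMES),
                                index=frame.index),
        map_mm=frame[map_col].rename("MAP_mm"),
        **kwargs,
    )


def write_calibration_table(ds: CalibrationDataset, path, sep=None) -> None:
    write_table(ds.to_frame(), path, sep=sep)


def read_profile_table(path, *, missing_as_zero: bool = True) -> DowncoreProfile:
    """Read a downcore profile ordered by a strictly increasing ``depth_m``.

    Compound and n-alkane columns are optional; whatever is present is
    preserved.  Non-monotone depths raise :class:`OrderingError`.
    """
    frame = _read(path)
    if "depth_m" not in frame.columns:
        raise SchemaError(f"{path}: profile requires a depth_m column")
    rename = {}
    for col in frame.columns:
        try:
            rename[col] = canonical_name(str(col))
        except KeyError:
            continue
    frame = frame.rename(columns=rename)
    numeric_cols = [c for c in frame.columns if c != "sample_id"]
    frame = _numeric(frame, numeric_cols, path)
    return DowncoreProfile(frame)


def write_profile_table(profile: DowncoreProfile, path, sep=None) -> None:
    write_table(profile.table, path, sep=sep)


def read_control_points(path) -> pd.DataFrame:
    """Two-column control-point file: depth (m), age (ka BP)."""
    frame = _read(path)
    cols = list(frame.columns)
    if not {"depth_m", "age_ka"} <= set(cols):
        if len(cols) < 2:
            raise SchemaError(f"{path}: expected columns depth_m, age_ka")
        frame = frame.rename(columns={cols[0]: "depth_m", cols[1]: "age_ka"})
    return _numeric(frame[["depth_m", "age_ka"]], ["depth_m", "age_ka"], path)


def read_series(path) -> tuple[np.ndarray, np.ndarray]:
    """Two-column time series file: age (ka), value."""
    frame = _read(path)
    if frame.shape[1] < 2:
        raise SchemaError(f"{path}: expected two columns (age, value)")
    frame = _numeric(frame, list(frame.columns[:2]), path)
    return (frame.iloc[:, 0].to_numpy(dtype=float),
            frame.iloc[:, 1].to_numpy(dtype=float))


def write_table(frame: pd.DataFrame, path, sep=None) -> None:
    """Write a DataFrame as delimited text at full float precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep=sep or _sep_for(path), index=False)
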