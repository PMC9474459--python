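"""Susceptibility-weighted age-depth modelling for loess-paleosol profiles.

Between two chronological control points the accumulated sediment mass is
apportioned by magnetic susceptibility, treated as an accumulation-rate
indicator: with layers i = 1..n of thickness a_i and susceptibility s_i
between controls (T1, T2), the age at the base of layer m is

    T_m = T1 + (sum_{i<=m} a_i s_i) * (T2 - T1) / (sum_{i<=n} a_i s_i).

With constant susceptibility this reduces exactly to linear depth-age
interpolation.  Depths are metres below the profile top (increasing
downward); ages are ka BP (increasing downward).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import DowncoreProfile
from .errors import (DegenerateWeightsError, ExtrapolationError,
                     InsufficientDataError, OrderingError)
from .series import GriddedSeries

__all__ = ["AgeModel", "assign_ages", "assign_profile_ages",
           "resample_to_age_grid"]

_DEPTH_TOL = 1e-9  # metres; controls must sit on layer boundaries


@dataclass(frozen=True)
class AgeModel:
    """Ages at layer bases plus the weighting that produced them."""

    depths_m: np.ndarray         # base depth of each layer
    ages_ka: np.ndarray          # assigned age at each layer base
    control_depths_m: np.ndarray
    control_ages_ka: np.ndarray
    cumulative_weight: np.ndarray  # running sum of a_i * s_i (profile-wide)

    def age_at(self, depth_m: float) -> float:
        """Age at an arbitrary depth, linear within a layer."""
        if depth_m < self.control_depths_m[0] - _DEPTH_TOL or \
                depth_m > self.control_depths_m[-1] + _DEPTH_TOL:
            raise ExtrapolationError(
                f"depth {depth_m} m outside control span "
                f"[{self.control_depths_m[0]}, {self.control_depths_m[-1]}] m"
            )
        knots_d = np.concatenate(([self.control_depths_m[0]], self.depths_m))
        knots_t = np.concatenate(([self.control_ages_ka[0]], self.ages_ka))
        return float(np.interp(depth_m, knots_d, knots_t))


def _validate_controls(controls: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    cd = controls["depth_m"].to_numpy(dtype=float)
    ca = controls["age_ka"].to_numpy(dtype=float)
    if cd.size < 2:
        raise InsufficientDataError("need at least two control points")
    if not (np.diff(cd) > 0).all():
        raise OrderingError("control depths must strictly increase")
    if not (np.diff(ca) > 0).all():
        raise OrderingError("control ages must strictly increase with depth")
    return cd, ca


def assign_ages(thickness_m, susceptibility, controls: pd.DataFrame, *,
                top_depth_m: float | None = None,
                fallback_uniform: bool = False) -> AgeModel:
    """Assign an age to the base of every layer.

    Parameters
    ----------
    thickness_m, susceptibility : array-like
        Per-layer thickness (m, > 0) and magnetic susceptibility (>= 0),
        ordered top to bottom.
    controls : pandas.DataFrame
        Columns ``depth_m`` and ``age_ka``; each control depth must
        coincide with a layer boundary, and every layer must lie inside
        the control span.
    top_depth_m : float, optional
        Depth of the top of the first layer; defaults to the first
        control depth.
    fallback_uniform : bool
        If an interval's susceptibility weights all vanish, weight by
        thickness alone instead of raising.
    """
    a = np.asarray(thickness_m, dtype=float)
    s = np.asarray(susceptibility, dtype=float)
    if a.ndim != 1 or a.size == 0 or (a <= 0).any():
        raise ValueError("layer thicknesses must be positive")
    if s.shape != a.shape or (s < 0).any() or not np.isfinite(s).all():
        raise ValueError("susceptibilities must be finite and >= 0")
    cd, ca = _validate_controls(controls)

    top = cd[0] if top_depth_m is None else float(top_depth_m)
    bases = top + np.cumsum(a)
    boundaries = np.concatenate(([top], bases))
    if cd[0] < top - _DEPTH_TOL or cd[-1] > bases[-1] + _DEPTH_TOL:
        raise ExtrapolationError(
            "control span exceeds the layered profile; trim the controls"
        )
    if bases[-1] > cd[-1] + _DEPTH_TOL or top < cd[0] - _DEPTH_TOL:
        raise ExtrapolationError(
            "layers extend outside the control span; ages would be "
            "extrapolated"
        )

    # locate each control on a layer boundary
    ctrl_idx = []
    for d in cd:
        j = int(np.argmin(np.abs(boundaries - d)))
        if abs(boundaries[j] - d) > 1e-6:
            raise OrderingError(
                f"control depth {d} m does not coincide with a layer boundary"
            )
        ctrl_idx.append(j)

    weights = a * s
    ages = np.empty_like(bases)
    for k in range(len(cd) - 1):
        lo, hi = ctrl_idx[k], ctrl_idx[k + 1]   # boundary indices
        w = weights[lo:hi]
        total = w.sum()
        if total <= 0:
            if not fallback_uniform:
                raise DegenerateWeightsError(
                    f"all susceptibility weights vanish between controls "
                    f"{cd[k]} m and {cd[k + 1]} m; pass fallback_uniform=True "
                    f"to weight by thickness alone"
                )
            w = a[lo:hi]
            total = w.sum()
        ages[lo:hi] = ca[k] + np.cumsum(w) * (ca[k + 1] - ca[k]) / total
    # exact control ages at control boundaries that are layer bases
    for j, age in zip(ctrl_idx, ca):
        if j > 0:
            ages[j - 1] = age
    return AgeModel(depths_m=bases, ages_ka=ages,
                    control_depths_m=cd, control_ages_ka=ca,
                    cumulative_weight=np.cumsum(weights))


def assign_profile_ages(profile: DowncoreProfile, controls: pd.DataFrame, *,
                        susceptibility_column: str = "susceptibility",
                        top_depth_m: float | None = None,
                        fallback_uniform: bool = False) -> DowncoreProfile:
    """Age every profile row, treating each sampling interval as one layer.

    Row depths are layer bases; the top of the first layer defaults to the
    first control depth.  Returns a new profile with an ``age_ka`` column.
    """
    if susceptibility_column not in profile.table.columns:
        raise KeyError(f"profile lacks column {susceptibility_column!r}")
    cd, _ = _validate_controls(controls)
    top = cd[0] if top_depth_m is None else float(top_depth_m)
    depths = profile.depth_m
    thickness = np.diff(np.concatenate(([top], depths)))
    model = assign_ages(
        thickness, profile.table[susceptibility_column].to_numpy(dtype=float),
        controls, top_depth_m=top, fallback_uniform=fallback_uniform,
    )
    return profile.with_ages(model.ages_ka)


def resample_to_age_grid(ages_ka, values, step_ka: float = 1.0
                         ) -> GriddedSeries:
    """Linear interpolation onto a uniform age grid (default 1 ka).

    The grid covers only the sampled overlap; see
    :meth:`GriddedSeries.from_samples`.
    """
    return GriddedSeries.from_samples(ages_ka, values, step_ka=step_ka)
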