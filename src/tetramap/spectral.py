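"""Continuous and cross wavelet analysis, plus PCA of factor matrices.

The cross wavelet spectrum of two series on a common uniform age grid is
the product of one continuous wavelet transform with the complex conjugate
of the other, ``CS = W1 * conj(W2)``.  Its modulus locates shared
periodicity; its argument is the local phase difference between the two
series at each (age, period) cell.

Conventions
-----------
* Mother wavelet: complex Morlet with dimensionless centre frequency 6,
  the standard choice in paleoclimate work (good period localisation).
* ``arg(CS) = phase(series1) - phase(series2)``: a positive phase means
  series 1 leads; pi (arrows pointing left in the usual quiver rendering)
  means the two series are anti-phased.
* Edges are zero-padded by the transform; coefficients inside the cone of
  influence (within sqrt(2) e-folding times of either end) are masked and
  excluded from band statistics by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .errors import InsufficientDataError, TetramapError
from .series import GriddedSeries

__all__ = ["cwt", "cross_wavelet", "band_phase", "pca_summary",
           "CwtResult", "CrossSpectrum", "PcaSummary", "BandPhase"]

#: Morlet dimensionless centre frequency (omega_0)
OMEGA0 = 6.0
#: pywt centre frequency (cycles per unit time at scale 1): omega_0 / 2 pi
_FC = OMEGA0 / (2.0 * np.pi)
#: pywt wavelet spec matching the analytic Morlet exp(-t^2/2) envelope
_WAVELET = f"cmor2.0-{_FC:.12f}"
#: scales per octave in the dyadic scale set
VOICES_PER_OCTAVE = 12
#: cone-of-influence e-folding distance is sqrt(2) * scale
_COI_EFOLD = np.sqrt(2.0)

_MIN_LENGTH = 16


def _scaleset(n: int, dt: float) -> np.ndarray:
    """Dyadic scales spanning periods [2*dt, n*dt/2]."""
    s0 = 2.0 * _FC  # scale (in samples) whose period is 2*dt
    smax = (n / 2.0) * _FC
    n_oct = np.log2(smax / s0)
    j = np.arange(int(np.floor(n_oct * VOICES_PER_OCTAVE)) + 1)
    return s0 * 2.0 ** (j / VOICES_PER_OCTAVE)


@dataclass(frozen=True)
class CwtResult:
    """Complex Morlet coefficient field of one series."""

    coefficients: np.ndarray   # (n_scales, n_times), complex
    periods_ka: np.ndarray     # (n_scales,)
    ages_ka: np.ndarray        # (n_times,)
    coi_mask: np.ndarray       # True where inside the cone of influence

    @property
    def power(self) -> np.ndarray:
        return np.abs(self.coefficients) ** 2


def _coi_mask(periods: np.ndarray, ages: np.ndarray) -> np.ndarray:
    """True where a coefficient sits inside the cone of influence.

    The Morlet e-folding time at Fourier period p is sqrt(2) * s with
    s = p * fc, so the maximum trustworthy period at distance d from the
    nearer edge is d / (sqrt(2) * fc).
    """
    edge = np.minimum(ages - ages[0], ages[-1] - ages)
    max_period = edge / (_COI_EFOLD * _FC)
    return periods[:, None] > max_period[None, :]


def cwt(series: GriddedSeries) -> CwtResult:
    """Continuous Morlet wavelet transform over a dyadic scale set.

    Periods span [2*step, span/2].  Requires at least 16 samples on a
    uniform grid (use :func:`tetramap.agemodel.resample_to_age_grid`
    first for irregular data).
    """
    if not isinstance(series, GriddedSeries):
        raise TypeError("cwt expects a GriddedSeries; resample irregular "
                        "data with resample_to_age_grid")
    n = len(series)
    if n < _MIN_LENGTH:
        raise InsufficientDataError(
            f"series of length {n} too short for wavelet analysis "
            f"(need >= {_MIN_LENGTH})"
        )
    dt = series.step_ka
    scales = _scaleset(n, dt)
    coef, freqs = pywt.cwt(series.values - series.values.mean(), scales,
                           _WAVELET, sampling_period=dt, method="fft")
    periods = 1.0 / freqs
    ages = series.ages_ka
    return CwtResult(coefficients=coef, periods_ka=periods, ages_ka=ages,
                     coi_mask=_coi_mask(periods, ages))


@dataclass(frozen=True)
class CrossSpectrum:
    """Cross wavelet spectrum of two series on a shared grid."""

    values: np.ndarray        # complex CS(b, a)
    periods_ka: np.ndarray
    ages_ka: np.ndarray
    coi_mask: np.ndarray

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def phase(self) -> np.ndarray:
        """Phase difference (series1 minus series2), radians in (-pi, pi]."""
        return np.angle(self.values)


def cross_wavelet(s1: GriddedSeries, s2: GriddedSeries) -> CrossSpectrum:
    """Cross wavelet spectrum ``W1 * conj(W2)`` of two gridded series.

    Both series must share the identical uniform grid.
    """
    s1.require_same_grid(s2)
    w1 = cwt(s1)
    w2 = cwt(s2)
    return CrossSpectrum(values=w1.coefficients * np.conj(w2.coefficients),
                         periods_ka=w1.periods_ka, ages_ka=w1.ages_ka,
                         coi_mask=w1.coi_mask)


@dataclass(frozen=True)
class BandPhase:
    """Power-weighted mean phase inside one period band."""

    period_ka: float
    mean_phase: float        # radians in (-pi, pi]
    antiphase: bool
    n_cells: int             # coefficients contributing (outside the cone)


def band_phase(cs: CrossSpectrum, period_ka: float, *,
               tolerance: float = 0.5, band_width: float = 0.25,
               include_cone: bool = False) -> BandPhase:
    """Mean cross-wavelet phase in a band around ``period_ka``.

    The band covers periods within a factor ``1 + band_width`` of the
    target.  The mean is the amplitude-weighted circular mean over all
    band coefficients outside the cone of influence.  The anti-phase
    verdict is True when the mean phase is within ``tolerance`` radians
    of +/-pi.

    Raises
    ------
    TetramapError
        If the band lies outside the resolved period range, or every
        band coefficient falls inside the cone of influence.
    """
    lo, hi = period_ka / (1.0 + band_width), period_ka * (1.0 + band_width)
    sel = (cs.periods_ka >= lo) & (cs.periods_ka <= hi)
    if not sel.any():
        raise TetramapError(
            f"period {period_ka} ka outside resolved range "
            f"[{cs.periods_ka.min():.3g}, {cs.periods_ka.max():.3g}] ka"
        )
    vals = cs.values[sel]
    if not include_cone:
        keep = ~cs.coi_mask[sel]
        if not keep.any():
            raise TetramapError(
                f"the {period_ka} ka band lies entirely inside the cone of "
                f"influence; the series is too short for this period"
            )
        vals = vals[keep]
    total = vals.sum()
    phase = float(np.angle(total))
    wrapped = np.angle(np.exp(1j * (phase - np.pi)))
    return BandPhase(period_ka=float(period_ka), mean_phase=phase,
                     antiphase=bool(abs(wrapped) < tolerance),
                     n_cells=int(vals.size))


@dataclass(frozen=True)
class PcaSummary:
    """Principal component decomposition of a samples x factors matrix."""

    variance_fractions: np.ndarray   # non-increasing, sums to 1
    loadings: np.ndarray             # (n_components, n_factors), orthonormal
    scores: np.ndarray               # (n_samples, n_components)
    factor_names: tuple[str, ...]


def pca_summary(matrix, *, standardize: bool = True) -> PcaSummary:
    """PCA of an environmental-factor matrix (samples as rows).

    With ``standardize=True`` (the default, appropriate for mixed-unit
    factors) each column is centred and scaled to unit variance first;
    a constant column then raises a zero-variance error.
    """
    import pandas as pd
    from sklearn.decomposition import PCA

    if isinstance(matrix, pd.DataFrame):
        names = tuple(str(c) for c in matrix.columns)
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        names = tuple(f"f{j}" for j in range(X.shape[1]))
    if X.ndim != 2 or X.shape[1] < 2 or X.shape[0] < 3:
        raise InsufficientDataError("PCA needs >= 3 samples and >= 2 factors")
    if not np.isfinite(X).all():
        raise ValueError("PCA input must have no missing cells")
    X = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            raise ValueError(
                f"zero-variance column(s) under standardization: "
                f"{[names[j] for j in zero]}"
            )
        X = X / sd
    pca = PCA(n_components=min(X.shape), svd_solver="full")
    scores = pca.fit_transform(X)
    frac = pca.explained_variance_ratio_
    return PcaSummary(variance_fractions=frac / frac.sum(),
                      loadings=pca.components_, scores=scores,
                      factor_names=names)


def normality_check(matrix) -> dict[str, float]:
    """Shapiro-Wilk p-value per column (advisory; normality not enforced)."""
    import pandas as pd
    from scipy import stats

    frame = matrix if isinstance(matrix, pd.DataFrame) else (
        pd.DataFrame(np.asarray(matrix, dtype=float)))
    return {str(c): float(stats.shapiro(frame[c].to_numpy()).pvalue)
            for c in frame.columns}
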