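"""Closed-form lipid proxy indices and climate calibrations.

brGDGT indices
--------------
* ``mbt_prime`` — methylation index over the 5-methyl + tetramethylated
  pool; reads as a relative soil-water-content indicator where the
  6-methyl isomer ratio exceeds 0.5.
* ``mbt_prime_6me`` — methylation index over the 6-methyl pool.
* ``ir_6me`` — share of 6-methyl isomers in the brGDGT pool.
* ``cbt_prime`` / ``ph_from_cbt_prime`` — cyclization index and its linear
  soil-pH calibration (pH = 7.15 + 1.59 * CBT').
* four temperature calibrations: ``mat_mr``, ``mat_mr_simple``,
  ``mat_ssm`` and ``maat_weijers``.

Leaf-wax n-alkane indices
-------------------------
* ``cpi`` — carbon preference index (two printed variants).
* ``acl`` — abundance-weighted average chain length of odd C23-C33.

Every ratio with a vanishing denominator returns NaN (a flagged missing
value) rather than raising, so downcore batch runs survive degenerate
horizons.  All functions accept a single sample (pandas Series) or a batch
(DataFrame, one sample per row) and return a float or Series accordingly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .registry import COMPOUND_NAMES, SIX_METHYL

__all__ = [
    "mbt_prime", "mbt_prime_6me", "ir_6me", "cbt_prime", "cbt",
    "ph_from_cbt_prime", "mat_mr", "mat_mr_simple", "mat_ssm",
    "maat_weijers", "cpi", "acl", "compute_proxy_suite",
    "ALKANE_HOMOLOGS",
]

ALKANE_HOMOLOGS = tuple(f"C{n}" for n in range(23, 35))

_P = "′"


def _frame(fa):
    if isinstance(fa, pd.Series):
        return fa.to_frame().T, True
    return fa, False


def _out(values, index, squeeze, name):
    s = pd.Series(np.asarray(values, dtype=float), index=index, name=name)
    return float(s.iloc[0]) if squeeze else s


def _tot(frame, names):
    from .registry import canonical_names

    return frame[canonical_names(names)].to_numpy(dtype=float).sum(axis=1)


def _ratio(num, den):
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return out


def mbt_prime(fa):
    """Methylation index (Ia+Ib+Ic over the 5-methyl/tetra pool)."""
    f, squeeze = _frame(fa)
    num = _tot(f, ["Ia", "Ib", "Ic"])
    den = num + _tot(f, ["IIa", f"IIa{_P}", "IIb", f"IIb{_P}",
                         "IIc", f"IIc{_P}", "IIIa", f"IIIa{_P}"])
    return _out(_ratio(num, den), f.index, squeeze, "MBT_prime")


def mbt_prime_6me(fa):
    """Methylation index over the 6-methyl pool (Ia+Ib+Ic numerator)."""
    f, squeeze = _frame(fa)
    num = _tot(f, ["Ia", "Ib", "Ic"])
    den = num + _tot(f, [f"IIa{_P}", f"IIb{_P}", f"IIc{_P}", f"IIIa{_P}"])
    return _out(_ratio(num, den), f.index, squeeze, "MBT_prime_6ME")


def ir_6me(fa, *, penta_hexa_only: bool = False):
    """6-methyl isomer ratio.

    Default denominator is the full brGDGT pool; with
    ``penta_hexa_only=True`` the tetramethylated compounds (which have no
    positional isomer) are excluded from the denominator, the convention
    used by part of the literature.
    """
    f, squeeze = _frame(fa)
    num = _tot(f, sorted(SIX_METHYL))
    if penta_hexa_only:
        den = _tot(f, [c for c in COMPOUND_NAMES
                       if c not in ("Ia", "Ib", "Ic")])
    else:
        den = _tot(f, COMPOUND_NAMES)
    return _out(_ratio(num, den), f.index, squeeze, "IR_6ME")


def cbt_prime(fa):
    """Cyclization index: -log10 of (Ic + 6-methyl pool)/(Ia+Ib+Ic)."""
    f, squeeze = _frame(fa)
    num = _tot(f, ["Ic", f"IIa{_P}", f"IIb{_P}", f"IIc{_P}",
                   f"IIIa{_P}", f"IIIb{_P}", f"IIIc{_P}"])
    den = _tot(f, ["Ia", "Ib", "Ic"])
    ratio = _ratio(num, den)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(np.asarray(ratio) > 0, -np.log10(
            np.where(np.asarray(ratio) > 0, ratio, 1.0)), np.nan)
    return _out(out, f.index, squeeze, "CBT_prime")


def cbt(fa):
    """Classical cyclization index -log10((Ib+IIb)/(Ia+IIa))."""
    f, squeeze = _frame(fa)
    ratio = _ratio(_tot(f, ["Ib", "IIb"]), _tot(f, ["Ia", "IIa"]))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(np.asarray(ratio) > 0, -np.log10(
            np.where(np.asarray(ratio) > 0, ratio, 1.0)), np.nan)
    return _out(out, f.index, squeeze, "CBT")


def ph_from_cbt_prime(cbt_prime_value):
    """Soil pH from CBT': pH = 7.15 + 1.59 * CBT'."""
    arr = np.asarray(cbt_prime_value, dtype=float)
    out = 7.15 + 1.59 * arr
    return float(out) if np.isscalar(cbt_prime_value) or arr.ndim == 0 else (
        pd.Series(out, name="pH",
                  index=getattr(cbt_prime_value, "index", None)))


def mat_mr(fa):
    """Mean annual temperature, isomer-ratio calibration (degC)."""
    f, squeeze = _frame(fa)
    a = f[list(COMPOUND_NAMES)].astype(float)
    out = (7.17 + 17.1 * a["Ia"] + 25.9 * a["Ib"]
           + 34.4 * a["Ic"] - 28.6 * a["IIa"])
    return _out(out, f.index, squeeze, "MAT_mr")


def mat_mr_simple(fa):
    """Two-compound simplification of the isomer-ratio MAT calibration."""
    f, squeeze = _frame(fa)
    a = f[list(COMPOUND_NAMES)].astype(float)
    return _out(5.58 + 17.91 * a["Ia"] - 18.77 * a["IIa"],
                f.index, squeeze, "MAT_mr_simple")


def mat_ssm(fa):
    """Surface-soil-moisture-aware MAT calibration (degC)."""
    f, squeeze = _frame(fa)
    a = f[list(COMPOUND_NAMES)].astype(float)
    out = (20.9
           - 13.4 * (a["IIa"] + a[f"IIa{_P}"])
           - 17.2 * (a["IIIa"] + a[f"IIIa{_P}"])
           - 17.5 * (a["IIb"] + a[f"IIb{_P}"])
           + 11.2 * a["Ib"])
    return _out(out, f.index, squeeze, "MAT_SSM")


def maat_weijers(fa):
    """Mean annual air temperature from CBT and MBT' (degC)."""
    f, squeeze = _frame(fa)
    out = 0.81 - 5.67 * np.asarray(cbt(f)) + 31.0 * np.asarray(mbt_prime(f))
    return _out(out, f.index, squeeze, "MAAT")


def _alk(profile, ns):
    f, squeeze = _frame(profile)
    cols = [f"C{n}" for n in ns]
    arr = np.zeros((len(f), len(ns)))
    for j, c in enumerate(cols):
        if c in f.columns:
            arr[:, j] = f[c].to_numpy(dtype=float)
    return arr, f.index, squeeze


def cpi(alkanes, variant: int = 1):
    """Carbon preference index of n-alkanes (odd-over-even dominance).

    ``variant=1``: ((C23..C31 odd) + (C25..C33 odd)) / (2 * (C24..C32 even)).
    ``variant=2``: mean of (C25..C33 odd)/(C24..C32 even) and
    (C25..C33 odd)/(C26..C34 even).
    """
    if variant == 1:
        odd_lo, idx, squeeze = _alk(alkanes, (23, 25, 27, 29, 31))
        odd_hi, _, _ = _alk(alkanes, (25, 27, 29, 31, 33))
        even, _, _ = _alk(alkanes, (24, 26, 28, 30, 32))
        out = _ratio(odd_lo.sum(1) + odd_hi.sum(1), 2.0 * even.sum(1))
    elif variant == 2:
        odd, idx, squeeze = _alk(alkanes, (25, 27, 29, 31, 33))
        even_lo, _, _ = _alk(alkanes, (24, 26, 28, 30, 32))
        even_hi, _, _ = _alk(alkanes, (26, 28, 30, 32, 34))
        out = 0.5 * (_ratio(odd.sum(1), even_lo.sum(1))
                     + _ratio(odd.sum(1), even_hi.sum(1)))
    else:
        raise ValueError("variant must be 1 or 2")
    return _out(out, idx, squeeze, f"CPI{variant}")


def acl(alkanes):
    """Average chain length over odd homologs C23-C33."""
    ns = np.array([23, 25, 27, 29, 31, 33], dtype=float)
    arr, idx, squeeze = _alk(alkanes, (23, 25, 27, 29, 31, 33))
    return _out(_ratio(arr @ ns, arr.sum(1)), idx, squeeze, "ACL")


#: IR_6ME threshold above which MBT' is read as a soil-water-content signal
SWC_IR6ME_THRESHOLD = 0.5


def compute_proxy_suite(fa, alkanes=None, *,
                        ir6me_penta_hexa_only: bool = False) -> pd.DataFrame:
    """All indices for one or many samples in a single pass.

    Returns a DataFrame (one row per sample) with every index column,
    NaN where an index is undefined, and a boolean ``swc_interpretable``
    column that is True where IR_6ME > 0.5 — the regime in which MBT' can
    be read as a relative soil-water-content indicator.
    """
    f, _ = _frame(fa)
    out = pd.DataFrame(index=f.index)
    out["MBT_prime"] = np.asarray(mbt_prime(f))
    out["MBT_prime_6ME"] = np.asarray(mbt_prime_6me(f))
    out["IR_6ME"] = np.asarray(ir_6me(f, penta_hexa_only=ir6me_penta_hexa_only))
    out["CBT_prime"] = np.asarray(cbt_prime(f))
    out["CBT"] = np.asarray(cbt(f))
    out["pH"] = 7.15 + 1.59 * out["CBT_prime"]
    out["MAT_mr"] = np.asarray(mat_mr(f))
    out["MAT_mr_simple"] = np.asarray(mat_mr_simple(f))
    out["MAT_SSM"] = np.asarray(mat_ssm(f))
    out["MAAT"] = np.asarray(maat_weijers(f))
    out["swc_interpretable"] = out["IR_6ME"] > SWC_IR6ME_THRESHOLD
    if alkanes is not None:
        alk, _ = _frame(alkanes)
        out["CPI1"] = np.asarray(cpi(alk, 1))
        out["CPI2"] = np.asarray(cpi(alk, 2))
        out["ACL"] = np.asarray(acl(alk))
    return out
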