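"""Feature sets and dataset splitting for calibration models."""

from __future__ import annotations

from ..containers import CalibrationDataset

_P = "′"

#: default model inputs: Ia, Ic and the six 6-methyl isomers (the pool most
#: responsive to soil moisture and pH); Ib is excluded.
DEFAULT_FEATURES: tuple[str, ...] = (
    "Ia", "Ic", f"IIa{_P}", f"IIb{_P}", f"IIc{_P}",
    f"IIIa{_P}", f"IIIb{_P}", f"IIIc{_P}",
)

#: nine-input variant that adds Ib back
NINE_FEATURES: tuple[str, ...] = DEFAULT_FEATURES + ("Ib",)


def split_dataset(ds: CalibrationDataset, validation_fraction: float,
                  seed: int) -> tuple[CalibrationDataset, CalibrationDataset]:
    """Uniformly random, disjoint, exhaustive training/validation split.

    Thin alias of :meth:`CalibrationDataset.split`; with n = 712 and
    validation_fraction = 179/712 the sizes are exactly 533/179.
    """
    return ds.split(validation_fraction, seed)
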