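"""Shared fixtures and hypothesis configuration."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings, strategies as st

from tetramap.registry import COMPOUND_NAMES

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_fa(**fractions) -> pd.Series:
    """A 15-compound fractional-abundance Series; unnamed compounds 0."""
    s = pd.Series(0.0, index=list(COMPOUND_NAMES))
    prime = "′"
    for key, value in fractions.items():
        name = key.replace("p", prime) if key.endswith("p") else key
        s[name] = value
    return s


@pytest.fixture
def fa_factory():
    return make_fa


@st.composite
def simplex_vectors(draw, n=15):
    """Random points on the n-simplex (strictly positive total)."""
    raw = draw(st.lists(st.floats(min_value=0.0, max_value=1.0,
                                  allow_nan=False),
                        min_size=n, max_size=n))
    total = sum(raw)
    if total <= 0:
        raw = [1.0] * n
        total = float(n)
    return np.asarray(raw) / total


@pytest.fixture(scope="session")
def small_calibration():
    from tetramap.synthetic import GeneratorConfig, generate_calibration_dataset

    ds, truth = generate_calibration_dataset(
        GeneratorConfig(n=160, seed=11))
    return ds, truth
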