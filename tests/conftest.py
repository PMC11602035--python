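"""Shared fixtures.

The heavy phase-space computations (10^4-beat chaotic series) are
session-scoped so the full non-linear chain runs once and is shared by
the unit and acceptance tests.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from easyhrv import BeatSeries
from easyhrv.nonlinear import compute_nonlinear_indices
from easyhrv.synthetic import SyntheticSpec, gen_rr


@pytest.fixture(scope="session")
def henon_series() -> BeatSeries:
    """~10^4 beats of Hénon-map RR dynamics (a=1.4, b=0.3)."""
    spec = SyntheticSpec(duration_s=8000.0, dynamics="henon", seed=3)
    series, _ = gen_rr(spec)
    assert len(series) >= 10_000
    return series


@pytest.fixture(scope="session")
def henon_nonlinear(henon_series):
    """Full non-linear index suite on the Hénon series (computed once)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return compute_nonlinear_indices(henon_series)


@pytest.fixture(scope="session")
def periodic_series() -> BeatSeries:
    """Strictly periodic RR pattern (period 40 beats, ~2000 beats)."""
    spec = SyntheticSpec(duration_s=1600.0, dynamics="periodic", seed=1)
    series, _ = gen_rr(spec)
    return series


@pytest.fixture(scope="session")
def periodic_nonlinear(periodic_series):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return compute_nonlinear_indices(periodic_series)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
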