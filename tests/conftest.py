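import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")

from trackway import SpeciesProfile, TrackwayRecord, default_specs, generate


@pytest.fixture
def profile() -> SpeciesProfile:
    """Default ptarmigan profile: h = 0.1727 m, g = 9.81 m/s^2."""
    return SpeciesProfile()


@pytest.fixture
def specs():
    return default_specs()


@pytest.fixture
def training_records(specs):
    """One seeded study-scale training dataset (n = 48 + 56 + 61)."""
    return generate(specs, seed=20170422)


def make_linear_records(slope, intercept, strides, gait="walking", noise=None):
    """Records lying on (or scattered about) an exact line, for oracles."""
    strides = np.asarray(strides, dtype=float)
    u = slope * strides + intercept
    if noise is not None:
        u = u + np.asarray(noise, dtype=float)
    return [
        TrackwayRecord(
            id=f"{gait}-{i}", l_stride=float(l), gait=gait, u_measured=float(v)
        )
        for i, (l, v) in enumerate(zip(strides, u))
    ]
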