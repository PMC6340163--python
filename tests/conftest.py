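import dataclasses

import pytest

from atriasim import (
    DEFAULT_ATRIAL_TIMERS,
    DEFAULT_SAN_TIMERS,
    LatticeSpec,
    NodeRegions,
    SimConfig,
)

SMALL_REGIONS = NodeRegions(san_rows=(4, 12), san_cols=(2, 4),
                            avn_rows=None, avn_cols=None)


@pytest.fixture
def small_config():
    """A 24x24 tissue small enough for brute-force oracles."""
    return SimConfig(
        spec=LatticeSpec(L=24, p_H=0.5, p_L=0.5),
        regions=SMALL_REGIONS,
        seed=7,
        total_steps=1200,
    )


@pytest.fixture
def dense_config():
    """Fully connected lattice: deterministic flat-front propagation."""
    return SimConfig(
        spec=LatticeSpec(L=24, p_H=1.0, p_L=1.0),
        regions=SMALL_REGIONS,
        atrial_timers=dataclasses.replace(DEFAULT_ATRIAL_TIMERS, r_noise=0),
        seed=3,
        total_steps=1500,
    )


@pytest.fixture
def t_san():
    t = DEFAULT_SAN_TIMERS
    return t.f + t.r0 + t.a
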