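import numpy as np
import pytest

from floragap.discovery_curves import DecadeSeries, decade_starts
from floragap.synthetic_data import SyntheticConfig, generate_name_table


@pytest.fixture(scope="session")
def default_cfg():
    return SyntheticConfig(seed=11, n_strata=2, true_asymptote=500)


@pytest.fixture(scope="session")
def name_table(default_cfg):
    return generate_name_table(default_cfg)


@pytest.fixture()
def series_factory():
    """Build a DecadeSeries from a cumulative curve sampled at t = 1..27."""

    def make(curve, noise_sd=0.0, rng=None, stratum="x"):
        starts = decade_starts()
        t = np.arange(1, len(starts) + 1, dtype=float)
        y = np.asarray(curve(t), dtype=float)
        if noise_sd:
            y = y + (rng or np.random.default_rng(0)).normal(0, noise_sd, size=len(t))
        y = np.maximum.accumulate(np.maximum(y, 0.0))
        described = np.diff(np.concatenate([[0.0], y]))
        return DecadeSeries(stratum, starts, described)

    return make
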