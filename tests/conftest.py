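import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from fishssf.config import SimulationConfig
from fishssf.synthetic import generate_hydraulic_rasters, reference_standardization

settings.register_profile("ci", derandomize=True, max_examples=40, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """A compact river used throughout the unit tests."""
    cfg = SimulationConfig(channel_length=200.0, channel_width=40.0,
                           pass_xy=(14.0, 20.0), release_xy=(180.0, 20.0),
                           n_fish=3, n_steps=150)
    cfg.validate()
    return cfg


@pytest.fixture(scope="session")
def small_stack(small_config):
    return generate_hydraulic_rasters(small_config, 50.0)


@pytest.fixture(scope="session")
def small_stz(small_stack, small_config):
    return reference_standardization(small_stack, small_config)


def make_detections(times_s, xs, ys, fish_id="F001", t0="2018-05-10T09:00:00Z"):
    base = pd.Timestamp(t0)
    return pd.DataFrame({
        "fish_id": fish_id,
        "time": base + pd.to_timedelta(np.asarray(times_s, dtype=float), unit="s"),
        "x": np.asarray(xs, dtype=float),
        "y": np.asarray(ys, dtype=float),
    })
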