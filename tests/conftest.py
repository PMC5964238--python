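import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_sim_config():
    """A desk-size assay: few cells, short recording, small field."""
    from casig.sim import SimConfig
    return SimConfig(n_tcells=12, n_mdms=8, n_frames=61,
                     field_size_um=(150.0, 150.0), seed=3)


def make_track(t_s, x_um, y_um, ratio, track_id=0):
    """Assemble a single-track DataFrame from parallel sequences."""
    t = np.asarray(t_s, dtype=float)
    return pd.DataFrame({
        "track_id": track_id,
        "frame": np.arange(len(t)),
        "t_s": t,
        "x_um": np.asarray(x_um, dtype=float),
        "y_um": np.asarray(y_um, dtype=float),
        "ratio": np.asarray(ratio, dtype=float),
    })
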