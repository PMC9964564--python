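import numpy as np
import pytest

from kinevar import KinematicTrial, MetricParams, RunConfig


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def default_params():
    return MetricParams()


@pytest.fixture
def default_config():
    return RunConfig()


@pytest.fixture
def random_trial(rng):
    """A 20 s, 240 Hz trial of mild 3D noise around an offset position."""
    n = 4800
    return KinematicTrial(
        x=10 + 0.05 * rng.standard_normal(n),
        y=-3 + 0.05 * rng.standard_normal(n),
        z=95 + 0.05 * rng.standard_normal(n),
        fs=240.0,
        participant_id="P01",
        condition="HoS",
        site="Hand",
        trial_index=1,
    )


def make_trial(coords, fs=100.0, **kwargs):
    coords = np.asarray(coords, dtype=float)
    defaults = dict(participant_id="P0", condition="HoS", site="Hand", trial_index=1)
    defaults.update(kwargs)
    return KinematicTrial(
        x=coords[:, 0], y=coords[:, 1], z=coords[:, 2], fs=fs, **defaults
    )
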