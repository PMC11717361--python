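import numpy as np
import pytest

from retseq.stimulus import (
    ChirpConfig,
    MovingBarStimulus,
    default_feature_windows,
    make_chirp,
    make_dense_noise,
)


@pytest.fixture(scope="session")
def chirp():
    return make_chirp(ChirpConfig())


@pytest.fixture(scope="session")
def bar():
    return MovingBarStimulus()


@pytest.fixture(scope="session")
def windows(chirp, bar):
    return default_feature_windows(chirp, bar)


@pytest.fixture(scope="session")
def small_noise():
    """Short dense-noise movie shared across tests."""
    return make_dense_noise(duration_s=60.0, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def gray_stimulus(duration_s=30.0, rate=50.0):
    """A constant mean-gray full-field stimulus (all non-gray segments empty)."""
    cfg = ChirpConfig(rate=rate, lead_gray_s=duration_s, on_step_s=0.0,
                      off_step_s=0.0, gray1_s=0.0, freq_sweep_s=0.0,
                      gray2_s=0.0, contrast_sweep_s=0.0, gray3_s=0.0)
    return make_chirp(cfg)
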