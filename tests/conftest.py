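import numpy as np
import pytest

import cavesong as cs

FS = 44_100.0


@pytest.fixture(scope="session")
def quiet_single_scape():
    """30 single clicks at amplitude/noise = 10 (easy detection regime)."""
    return cs.random_soundscape(n_singles=30, duration=60.0,
                                click=cs.ClickSpec(amplitude=0.5),
                                noise_rms=0.05, seed=11, min_gap=1.6)


@pytest.fixture(scope="session")
def ratio5_single_scape():
    """40 single clicks at the harder amplitude/noise = 5 regime."""
    return cs.random_soundscape(n_singles=40, duration=80.0,
                                click=cs.ClickSpec(amplitude=0.5),
                                noise_rms=0.1, seed=12, min_gap=1.6)


@pytest.fixture(scope="session")
def ratio5_serial_scape():
    """15 jittered 8-pulse serial trains at amplitude/noise = 5."""
    serial = cs.SerialSpec(pulse_count=8, interpulse=0.015,
                           jitter_fraction=0.1,
                           pulse=cs.ClickSpec(amplitude=0.5))
    return cs.random_soundscape(n_serials=15, duration=40.0, serial=serial,
                                noise_rms=0.1, seed=13, min_gap=1.6)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def template_from(rec, ann, duration=0.005):
    """Reference template cut at the first ground-truth click."""
    from cavesong.detection import ClickTemplate

    return ClickTemplate.from_recording(rec, ann.entries[0].time, duration)
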