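import warnings

import numpy as np
import pytest

import rhythmfit as rf


@pytest.fixture(autouse=True)
def _quiet_span_warnings():
    # the 6-50 h search range deliberately exceeds the 48 h design span
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*exceeds the.*span.*")
        yield


@pytest.fixture
def h16n2_bmal1():
    return rf.PRESETS["H16N2"]["BMAL1"]


@pytest.fixture
def h16n2_per2():
    return rf.PRESETS["H16N2"]["PER2"]


@pytest.fixture
def cos24():
    """Pure 24 h cosine, amplitude 1, peak at 6 h, around baseline 1."""
    return rf.DampedCosineParams(
        amplitude=1.0, damping_rate=0.0, phase=6.0, period=24.0, slope=0.0, intercept=1.0
    )


@pytest.fixture
def flat():
    """No oscillation, flat baseline at 1."""
    return rf.DampedCosineParams(
        amplitude=0.0, damping_rate=0.0, phase=0.0, period=24.0, slope=0.0, intercept=1.0
    )


def make_tc(params, noise_sd=0.0, seed=0, **kw):
    return rf.generate_timecourse(
        rf.GeneratorConfig(params=params, noise_sd=noise_sd, seed=seed, **kw)
    )


@pytest.fixture
def tc_factory():
    return make_tc


@pytest.fixture
def white_noise_factory(flat):
    def make(seed, sd=1.0):
        return rf.generate_null(
            rf.GeneratorConfig(params=flat, noise_sd=sd, seed=seed)
        )

    return make
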