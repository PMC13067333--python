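import numpy as np
import pytest

from tempopred import TaskDesign, build_bank, standard_layout


@pytest.fixture(scope="session")
def design250():
    """Task design at a reduced sampling rate for fast simulation."""
    return TaskDesign(sampling_rate=250)


@pytest.fixture(scope="session")
def layout16():
    return standard_layout(16)


@pytest.fixture(scope="session")
def layout64():
    return standard_layout(64)


@pytest.fixture(scope="session")
def small_bank():
    """12 wavelets, 1-40 Hz at 250 Hz: fast but spans delta through beta."""
    return build_bank(1.0, 40.0, 12, fs=250)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
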