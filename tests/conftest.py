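import numpy as np
import pytest

from dicmflex.preprocessing import filterbank, make_windows
from dicmflex.signal_io import LobarLayout, Recording
from dicmflex.synthetic_data import CouplingEntry, gen_recording


@pytest.fixture(scope="session")
def small_recording() -> Recording:
    """Two-channel 10-s null recording at 170 Hz."""
    return gen_recording(2, 170.0, 10.0, None, seed=100)


@pytest.fixture(scope="session")
def planted_iplv_recording() -> Recording:
    """Constant-lag alpha1 phase coupling on the single channel pair."""
    entry = CouplingEntry((0, 1), "iplv", "alpha1", strength=0.9)
    return gen_recording(2, 170.0, 10.0, [entry], seed=101)


@pytest.fixture(scope="session")
def small_banded(small_recording):
    return filterbank(small_recording)


@pytest.fixture(scope="session")
def small_scheme(small_recording):
    return make_windows(small_recording)


@pytest.fixture(scope="session")
def toy_layout() -> LobarLayout:
    """Four channels: one frontal and one temporal sensor per hemisphere."""
    return LobarLayout({
        "ch0": ("frontal", "L"),
        "ch1": ("frontal", "R"),
        "ch2": ("temporal", "L"),
        "ch3": ("temporal", "R"),
    })


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
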