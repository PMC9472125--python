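import numpy as np
import pytest

from neurorp.core_io import ChannelInfo, Recording
from neurorp.synthgen import ProtocolSpec, SubjectProfile, build_schedule


@pytest.fixture(scope="session")
def default_protocol() -> ProtocolSpec:
    return ProtocolSpec()


@pytest.fixture(scope="session")
def default_schedules(default_protocol):
    return build_schedule(default_protocol, seed=0)


@pytest.fixture(scope="session")
def tiny_protocol() -> ProtocolSpec:
    """One session, one series per condition — fast enough for signal tests."""
    return ProtocolSpec(n_sessions=1, series_per_condition_per_session=1)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_eeg_recording(data: np.ndarray, rate: float = 1000.0) -> Recording:
    channels = [ChannelInfo(label=f"EEG{i:02d}") for i in range(data.shape[0])]
    return Recording(data=data, rate=rate, channels=channels, modality="eeg")


@pytest.fixture
def sine_recording(rng):
    """Helper factory: multichannel recording holding one pure sinusoid."""

    def _make(freq: float, rate: float, duration_s: float = 20.0, n_channels: int = 1):
        t = np.arange(int(duration_s * rate)) / rate
        data = np.tile(np.sin(2 * np.pi * freq * t), (n_channels, 1))
        return make_eeg_recording(data, rate)

    return _make
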