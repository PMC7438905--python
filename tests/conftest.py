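import numpy as np
import pytest

from restmmn.datatypes import EventList, Recording
from restmmn.simulate import OddballGenParams, RestingGenParams, generate_oddball_recording, generate_resting_recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def short_resting():
    """60 s resting recording at the default coupling, 19 channels."""
    return generate_resting_recording(RestingGenParams(seed=7, duration_s=60.0))


@pytest.fixture(scope="session")
def clean_oddball():
    """Noise-free oddball session: MMN depth 3 uV peaking at 180 ms."""
    return generate_oddball_recording(
        OddballGenParams(seed=11, noise_sd=0.0, artifact_rate=0.0,
                         mmn_amplitude_uv=3.0, mmn_latency_ms=180.0)
    )


@pytest.fixture
def tiny_recording():
    """Hand-built 3-channel recording with two events."""
    fs = 500.0
    t = np.arange(int(5 * fs)) / fs
    sig = np.vstack([np.sin(2 * np.pi * 10 * t), np.cos(2 * np.pi * 10 * t), t])
    events = EventList(
        onsets=np.array([1.0, 2.5]),
        conditions=np.array(["standard", "deviant"], dtype=object),
        durations_ms=np.array([100.0, 50.0]),
    )
    return Recording(
        signal=sig,
        fs=fs,
        channel_labels=["Fz", "Cz", "Pz"],
        events=events,
        subject_id="S01",
        group_label="HC",
    )
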