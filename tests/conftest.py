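import numpy as np
import pytest

from restwise.eeg_io import Recording
from restwise.synthetic_data import default_montage


@pytest.fixture(scope="session")
def montage16():
    return default_montage(16)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_recording(rng, montage16) -> Recording:
    """2 s of random 16-channel EEG-like data at 250 Hz, with positions."""
    labels, pos = montage16
    data = rng.normal(scale=20.0, size=(16, 500))
    return Recording(
        data=data,
        srate=250.0,
        channel_labels=labels,
        channel_positions=pos,
        subject_id="S001",
        session="T1",
    )


def make_recording(data, srate=250.0, labels=None, **kw) -> Recording:
    data = np.asarray(data, dtype=float)
    if labels is None:
        labels = [f"E{i + 1:02d}" for i in range(data.shape[0])]
    return Recording(data=data, srate=srate, channel_labels=labels, **kw)
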