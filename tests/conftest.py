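import numpy as np
import pytest

from seizpred.eeg_io import EEGRecord, SeizureAnnotation


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def make_record():
    """Factory for small in-memory records."""

    def _make(
        n_channels=4,
        fs=256.0,
        duration=60.0,
        record_id="recA",
        data=None,
        seed=0,
    ):
        n = int(round(duration * fs))
        if data is None:
            data = np.random.default_rng(seed).standard_normal((n_channels, n)) * 20
        return EEGRecord(
            record_id=record_id,
            data=data,
            fs=fs,
            channel_names=[f"CH{i + 1:02d}" for i in range(n_channels)],
        )

    return _make


@pytest.fixture
def annotation():
    def _make(record_id="recA", onset=18000.0, offset=18120.0):
        return SeizureAnnotation(record_id, onset, offset)

    return _make
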