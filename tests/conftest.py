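import tempfile

import numpy as np
import pytest
from hypothesis import settings
from hypothesis.configuration import set_hypothesis_home_dir

# keep hypothesis' scratch storage out of the repository
set_hypothesis_home_dir(tempfile.mkdtemp(prefix="hypothesis-"))

from qeeg.core import BandScheme, EEGRecording, build_standard_montage
from qeeg.preprocess import EpochSet

# deterministic property tests, no on-disk example database
settings.register_profile("deterministic", database=None, derandomize=True,
                          deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def montage():
    return build_standard_montage()


@pytest.fixture(scope="session")
def scheme():
    return BandScheme()


@pytest.fixture
def make_recording(montage):
    """Factory for quick multichannel recordings from a per-channel signal."""

    def _make(signal=None, fs=512.0, duration_s=10.0, annotations=(),
              n_channels=None, seed=0):
        n_ch = n_channels or montage.n_channels
        n = int(round(fs * duration_s))
        if signal is None:
            rng = np.random.default_rng(seed)
            data = rng.standard_normal((n_ch, n))
        else:
            signal = np.asarray(signal, dtype=float)
            data = np.tile(signal, (n_ch, 1))
        return EEGRecording(samples=data, fs=fs, montage=montage,
                            annotations=list(annotations))

    return _make


@pytest.fixture
def make_epochs(montage):
    """Factory for an EpochSet straight from an (E, C, T) array."""

    def _make(data, fs=512.0, epoch_length_s=None):
        data = np.asarray(data, dtype=float)
        length = epoch_length_s or data.shape[2] / fs
        return EpochSet(data=data, fs=fs, montage=montage,
                        epoch_length_s=length)

    return _make
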