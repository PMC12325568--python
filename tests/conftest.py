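import numpy as np
import pytest

from fpvs.montage import default_montage
from fpvs.paradigm import DesignSpec, build_sequence
from fpvs.preprocess import Epoch
from fpvs.simulate import NoiseSpec, ResponseSpec, simulate_recording


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture()
def design():
    return DesignSpec()


@pytest.fixture(scope="session")
def quiet_response():
    """No neural response at all: recordings contain only background noise."""
    return ResponseSpec(standard_amp_uv=0.0, oddball_amp_uv=0.0)


@pytest.fixture(scope="session")
def clean_recording(montage):
    """One experimental recording with the default ground truth and nearly no
    noise, simulated at 512 Hz (shared across read-only tests)."""
    seq = build_sequence(DesignSpec(), seed=11)
    return simulate_recording(seq, ResponseSpec(),
                              NoiseSpec(noise_sd_uv=1e-6), montage,
                              fs_hz=512.0, seed=12)


def make_epoch(data, fs_hz=512.0, montage=None, **labels):
    return Epoch(np.asarray(data, dtype=float), fs_hz, 0.0, labels=dict(labels),
                 montage=montage)
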