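import numpy as np
import pytest

from dfhm.montage import Montage, standard_montage
from dfhm.recording import EEGRecording
from dfhm.synthetic import GeneratorConfig, WorkloadProfile, generate_eeg


@pytest.fixture(scope="session")
def montage():
    return standard_montage()


@pytest.fixture(scope="session")
def toy_montage():
    """Minimal 3-channel chain a–b–c used for hand-computable spatial tests."""
    names = ("Fp1", "Cz", "O1")
    positions = {"Fp1": (0.0, 1.0), "Cz": (0.0, 0.0), "O1": (0.0, -1.0)}
    neighbours = {"Fp1": ("Cz",), "Cz": ("Fp1", "O1"), "O1": ("Cz",)}
    return Montage(
        channel_names=names,
        positions=positions,
        neighbours=neighbours,
        frontal_set=("Fp1",),
        parietal_set=("O1",),
    )


@pytest.fixture(scope="session")
def clean_recording(montage):
    """60 s of artifact-free synthetic EEG at a constant moderate level."""
    profile = WorkloadProfile.constant("moderate", 60.0)
    return generate_eeg(profile, GeneratorConfig(seed=11))


def make_recording(samples, montage, fs=500.0):
    return EEGRecording(np.asarray(samples, dtype=float), fs, montage)
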