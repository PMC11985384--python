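import numpy as np
import pytest

from somnoagree.preprocess import condition_signal, spectrogram_epochs
from somnoagree.stages import Hypnogram
from somnoagree.synthgen import (
    default_architecture,
    default_recipe,
    generate_hypnogram,
    synthesize_biopotential,
)


def make_patient(seed: int, epochs: int = 120, recipe=None, invalid_epochs=()):
    """Synthetic patient: (spectrogram epochs, ground-truth hypnogram)."""
    recipe = recipe or default_recipe()
    hyp = generate_hypnogram(default_architecture(epochs, seed=seed))
    record = synthesize_biopotential(hyp, recipe, seed=seed + 5000)
    spec = spectrogram_epochs(condition_signal(record), invalid_epochs=invalid_epochs)
    return spec, hyp


@pytest.fixture(scope="session")
def tiny_cohort():
    """Four short patients shared by the model-level unit tests."""
    return [make_patient(s, epochs=60) for s in range(4)]


def stage_codes(symbols: str) -> Hypnogram:
    """Build a hypnogram from a compact string like 'W W N1 N2 R INV'."""
    m = {"W": 0, "N1": 1, "N2": 2, "N3": 3, "R": 4, "INV": 5}
    return Hypnogram(np.array([m[s] for s in symbols.split()], dtype=np.int8))
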