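import numpy as np
import pytest

from pupfuse.seq_io import Dataset, PeptideWindow, SequenceRecord
from pupfuse.synthetic_data import (PlantedEffect, SyntheticConfig,
                                    default_planted_config, generate)

RNG_SEED = 20260925


@pytest.fixture
def rng():
    return np.random.default_rng(RNG_SEED)


def random_window(rng, w=57, pad_left=0, pad_right=0, label=None):
    """A random tolerated-alphabet window with 'K' at center."""
    core = rng.choice(list("ARNDCQEGHILKMFPSTWYV"), size=w - pad_left - pad_right)
    chars = ["-"] * pad_left + list(core) + ["-"] * pad_right
    chars[(w - 1) // 2] = "K"
    return PeptideWindow("".join(chars), label=label)


@pytest.fixture
def small_planted_dataset():
    """120-window dataset with strong planted positional signal."""
    return generate(default_planted_config(n_pos=60, n_neg=60, effect=0.3, seed=11))


@pytest.fixture
def noise_dataset():
    """Pure-background dataset: labels carry no signal."""
    return generate(SyntheticConfig(n_pos=60, n_neg=60, seed=12))


@pytest.fixture
def toy_record():
    return SequenceRecord(id="p1", residues="MKRAAKLLWKPQRSTKVNDE")
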