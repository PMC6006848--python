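import numpy as np
import pytest

from samselect.seqdata import Dataset, codes_to_seq


def random_dataset(rng: np.random.Generator, t: int, n: int) -> Dataset:
    """Uniform random DNA dataset, ids seq0..seq{t-1}."""
    return Dataset(
        [(f"seq{i}", codes_to_seq(rng.integers(0, 4, n))) for i in range(t)]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_dataset(rng) -> Dataset:
    return random_dataset(rng, 5, 50)
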