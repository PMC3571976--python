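import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from kamh import generate_surname_like, make_example_fixtures
from kamh.ystr_io import HaplotypeDataset


@pytest.fixture(scope="session")
def example_i() -> HaplotypeDataset:
    """9 objects, 3 attributes, 3 tight classes with colliding plurality modes."""
    return make_example_fixtures()[0]


@pytest.fixture(scope="session")
def example_ii() -> HaplotypeDataset:
    """8 objects, 2 classes sized 6 and 2 (extreme skew)."""
    return make_example_fixtures()[1]


@pytest.fixture(scope="session")
def separable_dataset() -> HaplotypeDataset:
    """Well-separated surname-like data, 4 classes of 40 on 25 markers."""
    return generate_surname_like(
        4, [40] * 4, m=25, mismatch_probs={0: 0.4, 1: 0.3, 2: 0.2, 3: 0.1},
        seed=11,
    )


def random_categorical_dataset(rng: np.random.Generator, n: int, m: int,
                               alphabet: int = 4) -> HaplotypeDataset:
    """Small random token table for oracle comparisons."""
    values = np.array(
        [[str(int(t)) for t in rng.integers(0, alphabet, size=m)]
         for _ in range(n)],
        dtype=object,
    )
    return HaplotypeDataset(
        ids=tuple(f"o{i}" for i in range(n)),
        markers=tuple(f"M{j}" for j in range(m)),
        values=values,
    )
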