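import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests.oracles importable

from rnacurve import CharacteristicSequence, SimulationConfig, encode, random_structure

DIALECT = "ACGUacgu"


def random_dialect(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(DIALECT), size=n))


@pytest.fixture
def rng():
    return np.random.default_rng(20160523)


@pytest.fixture
def random_cs_batch(rng):
    """200 fuzzed characteristic sequences of assorted lengths."""
    return [
        CharacteristicSequence.from_dialect(random_dialect(rng, int(rng.integers(1, 60))), f"cs{i}")
        for i in range(200)
    ]


@pytest.fixture
def random_structures(rng):
    """Fuzzed valid structures of assorted sizes and pairing levels."""
    out = []
    for i in range(50):
        cfg = SimulationConfig(
            n=int(rng.integers(2, 80)),
            pair_fraction=float(rng.uniform(0, 0.9)),
            allow_pseudoknots=bool(rng.integers(2)),
            seed=int(rng.integers(2**31)),
        )
        out.append(random_structure(cfg, name=f"s{i}"))
    return out


@pytest.fixture
def encoded_batch(random_structures):
    return [encode(s) for s in random_structures]
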