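import functools
import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests/oracles.py

from crispex.candidate_finder import RunConfig
from crispex.fixtures import standard_fixture
from crispex.sequence_io import NucleotideSequence

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_residues(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


@functools.lru_cache(maxsize=None)
def get_standard_fixture(seed: int):
    return standard_fixture(seed)


@functools.lru_cache(maxsize=None)
def get_random_genome(seed: int, n_contigs: int = 1, length: int = 10_000):
    rng = np.random.default_rng(seed)
    return tuple(
        NucleotideSequence(f"c{i + 1}", random_residues(rng, length))
        for i in range(n_contigs)
    )


@pytest.fixture
def config():
    return RunConfig()


@pytest.fixture(scope="session")
def suite99():
    return get_standard_fixture(99)
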