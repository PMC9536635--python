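import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from forkasym.genome import Genome


@pytest.fixture(scope="session")
def toy_genome() -> Genome:
    """Two small chromosomes of deterministic random sequence (10 kb and
    6 kb), AT-rich enough to contain plenty of dipyrimidines."""
    rng = np.random.default_rng(20240)
    bases = np.frombuffer(b"ACGT", dtype="S1")

    def seq(n, p):
        return bases[rng.choice(4, size=n, p=p)].tobytes().decode()

    return Genome(
        {
            "chrA": seq(10_000, [0.3, 0.2, 0.2, 0.3]),
            "chrB": seq(6_000, [0.25, 0.25, 0.25, 0.25]),
        }
    )


@pytest.fixture(scope="session")
def flat_genome() -> Genome:
    """A 4-kb all-uniform chromosome for arithmetic-only tests."""
    rng = np.random.default_rng(77)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    return Genome({"chr1": bases[rng.integers(0, 4, 4000)].tobytes().decode()})
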