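import numpy as np
import pytest

from dnanchor import synthetic as syn
from dnanchor.dna_structure import BasePairing
from dnanchor.io_model import TrajectorySet


def child_seeds(base: int, n: int) -> list[int]:
    """Derive n independent sub-seeds (< 2^31) from one base seed."""
    return [int(s) for s in np.random.SeedSequence(base).generate_state(n) % (2**31)]


@pytest.fixture(scope="session")
def ideal_duplex():
    """Idealized 30-bp B-form proxy duplex with canonical step parameters."""
    return syn.gen_bdna(syn.BDnaParams())


@pytest.fixture(scope="session")
def pairing30():
    return BasePairing.from_duplex(30)


def single_frame(topology, coords, box=(100.0, 100.0, 100.0)):
    """Wrap one coordinate set as a 1-frame trajectory."""
    return TrajectorySet(topology, [0.0], [list(box)], np.asarray(coords)[None])
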