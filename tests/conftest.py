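import numpy as np
import pytest

from isoformgraph.seeding import Read

BASES = "ACGT"


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def make_read(read_id: str, sequence: str, cluster_id: str = "c") -> Read:
    return Read(
        read_id=read_id,
        sequence=sequence,
        quality="I" * len(sequence),
        cluster_id=cluster_id,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
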