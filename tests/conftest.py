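import numpy as np
import pytest

from ssrkit import PlantSpec, make_genome


@pytest.fixture(scope="session")
def planted_genome():
    """A small genome with a mix of plant types plus its truth table."""
    spec = PlantSpec(
        plants=(
            ("GAT", 5, None),
            ("AT", 8, 50),
            ("AAG", 6, None),
            ("A", 12, None),
            ("ACGT", 5, 0),
            ("AATC", 4, None),
        )
    )
    return make_genome(spec, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
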