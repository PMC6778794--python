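import numpy as np
import pytest
from hypothesis import settings

from gencross.genome import GeneticMap, generate_synthetic_founders

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def desk_panel():
    """Desk-scale founder panel: 800 inbred lines x 700 markers on 7 x 150 cM."""
    return generate_synthetic_founders(800, 700, 7, 150.0, 30, 1, seed=11)


@pytest.fixture(scope="session")
def tiny_panel():
    """Very small panel for structural and CLI tests."""
    return generate_synthetic_founders(120, 140, 7, 150.0, 20, 1, seed=3)


@pytest.fixture()
def two_locus_map_c01():
    """Two linked loci with recombination fraction exactly 0.1 (Haldane)."""
    d = -50.0 * np.log(1.0 - 2.0 * 0.1)  # invert the mapping function
    return GeneticMap(np.array(["A", "B"], dtype=object),
                      np.array([1, 1]), np.array([0.0, d]))
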