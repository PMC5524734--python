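import numpy as np
import pandas as pd
import pytest

import pedtrace as pt
from pedtrace.matrix import MISSING


@pytest.fixture
def tiny_matrix():
    """Handcrafted 3x4 matrix with one missing call."""
    return pt.GenotypeMatrix(
        ["i1", "i2", "i3"],
        ["L1", "L2", "L3", "L4"],
        np.array(
            [
                [0, 1, 2, 0],
                [2, MISSING, 1, 1],
                [1, 1, 0, 2],
            ],
            dtype=np.int8,
        ),
    )


@pytest.fixture(scope="session")
def small_population():
    """12 parents, 10 crosses, 30 loci — shared across assignment tests."""
    spec = pt.PopulationSpec(n_parents=12, n_loci=30, n_crosses=10, seed=7)
    parents, design, freqs = pt.generate_population(spec)
    return parents, design, freqs


@pytest.fixture(scope="session")
def small_progeny(small_population):
    parents, design, _ = small_population
    progeny, truth = pt.simulate_progeny_dataset(parents, design, n_per_cross=8, seed=11)
    return progeny, truth
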