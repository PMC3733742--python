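import numpy as np
import pytest

from svpls import ExpressionMatrix, GroupDesign, SimulationSpec, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def four_sample_design():
    return GroupDesign(np.array([1, 1, 2, 2]))


@pytest.fixture
def toy_matrix():
    """2 genes x 4 samples with equal replicates inside every cell."""
    return ExpressionMatrix(
        np.array([[1.0, 1.0, 3.0, 3.0], [2.0, 2.0, 2.0, 2.0]]),
        gene_ids=("g1", "g2"),
        sample_ids=("s1", "s2", "s3", "s4"),
    )


@pytest.fixture
def random_dataset(rng):
    """5 genes x 8 samples of pure noise around gene levels."""
    values = rng.normal(5.0, 1.0, size=(5, 8)) + rng.normal(0, 0.4, size=(5, 8))
    return (
        ExpressionMatrix(
            values,
            gene_ids=tuple(f"g{i}" for i in range(1, 6)),
            sample_ids=tuple(f"s{j}" for j in range(1, 9)),
        ),
        GroupDesign(np.repeat([1, 2], 4)),
    )


@pytest.fixture(scope="session")
def setting1_dataset():
    return simulate_dataset(SimulationSpec(seed=7))
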