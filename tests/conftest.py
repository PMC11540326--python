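import numpy as np
import pytest

from graphgwp import MarkerMatrix, PhenotypeVector, SimConfig, simulate_population


@pytest.fixture(scope="session")
def desk_population():
    """One small multi-generation population shared across tests."""
    return simulate_population(SimConfig.desk(seed=42))


@pytest.fixture
def tiny_markers():
    """4 individuals x 3 markers, fully typed, polymorphic."""
    return MarkerMatrix(
        ["a", "b", "c", "d"],
        ["m1", "m2", "m3"],
        np.array([[0, 1, 2], [1, 1, 0], [2, 0, 1], [0, 2, 2]], dtype=float),
    )


@pytest.fixture
def tiny_phenotypes():
    return PhenotypeVector(["a", "b", "c", "d"], np.array([1.0, 2.0, 3.0, 4.0]))


def random_marker_matrix(rng, n, p):
    """Random dosage matrix helper used by several oracle tests."""
    return MarkerMatrix(
        [f"i{k}" for k in range(n)],
        [f"m{j}" for j in range(p)],
        rng.integers(0, 3, size=(n, p)).astype(float),
    )
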