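import numpy as np
import pytest

from transientmpm import PopulationModel


def random_ergodic_matrix(rng: np.random.Generator, dim: int | None = None) -> np.ndarray:
    """Random non-negative matrix with a strictly positive first row and
    subdiagonal plus a positive diagonal entry => irreducible and primitive."""
    if dim is None:
        dim = int(rng.integers(2, 8))
    A = np.zeros((dim, dim))
    A[0, :] = rng.uniform(0.1, 3.0, dim)
    for j in range(dim - 1):
        A[j + 1, j] = rng.uniform(0.05, 0.95)
    A[0, 0] += 0.1
    # sprinkle extra entries
    mask = rng.random((dim, dim)) < 0.3
    A = A + mask * rng.uniform(0.0, 0.5, (dim, dim))
    return A


def random_stage_vector(rng: np.random.Generator, dim: int) -> np.ndarray:
    x = rng.uniform(0.0, 1.0, dim)
    x[rng.integers(0, dim)] += 0.5  # guarantee non-zero
    return x


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def two_matrix_population():
    rng = np.random.default_rng(42)
    return PopulationModel(
        population_id="pop_a",
        species_id="sp_a",
        growth_form="shrub",
        matrices=[random_ergodic_matrix(rng, 3) for _ in range(2)],
    )
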