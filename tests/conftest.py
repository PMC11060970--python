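import warnings

import numpy as np
import pytest

from cmlc import (
    MultilayerNetwork,
    SolverOptions,
    dependency_scenarios,
    three_layer_example,
    validate_dependency_matrix,
)


@pytest.fixture(scope="session")
def example_net() -> MultilayerNetwork:
    return three_layer_example()


@pytest.fixture(scope="session")
def scenarios():
    return dependency_scenarios()


@pytest.fixture
def tight_opts() -> SolverOptions:
    # eigenvalue deltas converge quadratically on symmetric layers, so the
    # eigenvector error is roughly the square root of the delta tolerance
    return SolverOptions(tol=1e-12)


def make_dependency(rows):
    """Validate a dependency matrix, silencing the negative-weight warning."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return validate_dependency_matrix(np.asarray(rows, float))


def random_connected_layer(p: int, rng: np.random.Generator) -> np.ndarray:
    """Random nonnegative strongly connected layer: ring + random weights."""
    A = rng.random((p, p)) * (rng.random((p, p)) < 0.5)
    for i in range(p):  # directed ring guarantees strong connectivity
        A[i, (i + 1) % p] += 0.5 + rng.random()
    np.fill_diagonal(A, 0.0)
    return A
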