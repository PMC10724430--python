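import numpy as np
import pytest

from dnbpipe import ExpressionMatrix, SimulationParams, simulate_sample

#: 6-cell x 4-marker toy matrix; the expected DNB statistics for the
#: module {A, B} were computed by an independent brute-force script
#: (plain loops over scipy.stats.pearsonr) and frozen in test_core.
TOY_VALUES = np.array([
    [0.0, 1.0, 2.0, 5.0],
    [1.0, 0.5, 2.0, 3.0],
    [2.0, 2.5, 1.0, 4.0],
    [3.0, 2.0, 3.0, 1.0],
    [4.0, 4.5, 0.5, 2.0],
    [5.0, 3.0, 1.5, 0.0],
])


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    return ExpressionMatrix(TOY_VALUES.copy(), ("A", "B", "C", "D"))


@pytest.fixture(scope="session")
def default_params() -> SimulationParams:
    return SimulationParams(seed=7)


@pytest.fixture(scope="session")
def planted_sample(default_params):
    """One fully responding patient with the default planted module."""
    return simulate_sample(default_params, "P01", amplitude=1.0)


@pytest.fixture(scope="session")
def small_params() -> SimulationParams:
    """8-marker panel with a planted triple: small enough for exhaustive
    module enumeration."""
    return SimulationParams(n_markers=8, module_markers=(2, 5, 7),
                            n_cells=3000, seed=11)
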