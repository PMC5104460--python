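import numpy as np
import pytest

from infoseek.optimal_dp import solve_cached
from infoseek.synthetic_data import PopulationSpec, generate_population
from infoseek.task_engine import Condition, Direction, Operation

MULTIPLY_BIG = Condition(Operation.MULTIPLY, Direction.BIG)
MULTIPLY_SMALL = Condition(Operation.MULTIPLY, Direction.SMALL)
ADD_BIG = Condition(Operation.ADD, Direction.BIG)
ADD_SMALL = Condition(Operation.ADD, Direction.SMALL)
MULTIPLY_PAIR = [MULTIPLY_BIG, MULTIPLY_SMALL]


@pytest.fixture(scope="session")
def qt_multiply_big():
    return solve_cached(MULTIPLY_BIG)


@pytest.fixture(scope="session")
def qt_multiply_small():
    return solve_cached(MULTIPLY_SMALL)


@pytest.fixture(scope="session")
def qt_multiply(qt_multiply_big, qt_multiply_small):
    return {MULTIPLY_BIG: qt_multiply_big, MULTIPLY_SMALL: qt_multiply_small}


@pytest.fixture(scope="session")
def optimal_multiply_dataset():
    """400 optimal agents on the multiply pair (two gameplays for retest)."""
    spec = PopulationSpec(n_subjects=400, policy="OPTIMAL",
                          conditions=Operation.MULTIPLY, n_gameplays=2,
                          seed=101)
    return generate_population(spec)


@pytest.fixture(scope="session")
def reduced_multiply_dataset():
    spec = PopulationSpec(n_subjects=500, policy="PARAMETRIC_REDUCED",
                          conditions=Operation.MULTIPLY, seed=202)
    return generate_population(spec)
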