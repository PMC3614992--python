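import numpy as np
import pytest

import chronoq as cq
from chronoq.similarity import SimilarityMatrix

# survival-sorted optimum of the embedded 10-sample benchmark, 0-based:
# S6, S3, S10, S5, S7, S9, S1, S8, S4, S2
SURVIVAL_OPTIMUM = (5, 2, 9, 4, 6, 8, 0, 7, 3, 1)
OPTIMUM_SIM = 53.01


@pytest.fixture(scope="session")
def table2():
    return cq.fixture_tables("table2_similarity")


@pytest.fixture(scope="session")
def table1():
    return cq.fixture_tables("table1_survival")


@pytest.fixture(scope="session")
def table3():
    return cq.fixture_tables("table3_timepoints")


@pytest.fixture(scope="session")
def table4():
    return cq.fixture_tables("table4_orderings")


def random_similarity(rng, n: int) -> SimilarityMatrix:
    """Random symmetric similarity instance on [1, 10)."""
    a = rng.uniform(1.0, 10.0, size=(n, n))
    a = (a + a.T) / 2.0
    return SimilarityMatrix([f"S{i + 1}" for i in range(n)], a)
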