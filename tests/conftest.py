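import numpy as np
import pytest

from iudcea import StrategyResult, paper_fixture


@pytest.fixture(scope="session")
def fixture_ps():
    return paper_fixture()


@pytest.fixture()
def table1_strategies():
    """The published ranking's four (cost, effectiveness) pairs."""
    return [
        StrategyResult("Pernambuco", 3_813.0, 4.3),
        StrategyResult("Scenario 1", 19_655.0, 4.5),
        StrategyResult("Scenario 2", 48_003.0, 4.0),
        StrategyResult("Scenario 3", 73_819.0, 3.7),
    ]


def random_strategies(rng: np.random.Generator, n: int, integer: bool = False):
    """Random strategy sets; integer grids provoke ties and collinearity."""
    if integer:
        costs = rng.integers(0, 8, size=n)
        effs = rng.integers(0, 8, size=n)
    else:
        costs = rng.uniform(0, 100_000, size=n)
        effs = rng.uniform(0, 10, size=n)
    return [
        StrategyResult(f"s{i}", float(costs[i]), float(effs[i])) for i in range(n)
    ]
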