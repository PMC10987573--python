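import numpy as np
import pandas as pd
import pytest

from catchstat import CommunityTable, ConfoundingScenario, confounding_scenario


@pytest.fixture
def simple_table() -> CommunityTable:
    return CommunityTable(pd.DataFrame(
        {"poverty": [10.0, 20.0, 30.0, 40.0, 50.0],
         "mortality": [5.0, 9.0, 16.0, 19.0, 26.0]},
        index=["A", "B", "C", "D", "E"]))


@pytest.fixture
def confounded_table():
    """Pure-confounding triangle at n=200, fixed seed, with ground truth."""
    return confounding_scenario(ConfoundingScenario(n=200, seed=11))


def make_table(columns: dict, ids=None) -> CommunityTable:
    df = pd.DataFrame(columns)
    if ids is None:
        ids = [f"R{i:03d}" for i in range(1, len(df) + 1)]
    df.index = ids
    return CommunityTable(df)


def random_correlation_matrix(p: int, rng: np.random.Generator) -> np.ndarray:
    """A random full-rank correlation matrix via normalized Gram matrix."""
    A = rng.standard_normal((p, p + 2))
    S = A @ A.T
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)
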