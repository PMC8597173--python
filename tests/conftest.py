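import itertools

import numpy as np
import pytest

import dmocea as d


@pytest.fixture(scope="session")
def default_cfg() -> d.ScenarioConfig:
    return d.default_config()


@pytest.fixture(scope="session")
def bank(default_cfg):
    """Synthetic matrix bank of the base case (seed fixed by the config)."""
    return d.resolve_matrices(default_cfg)


@pytest.fixture(scope="session")
def dex() -> d.TreatmentStrategy:
    from dmocea import defaults
    return defaults.dexamethasone_strategy()


@pytest.fixture(scope="session")
def ta() -> d.TreatmentStrategy:
    from dmocea import defaults
    return defaults.triamcinolone_strategy()


def make_matrix(strategy_id: str, period: str, rows) -> d.TransitionMatrix:
    return d.TransitionMatrix(strategy_id=strategy_id, period=period,
                              p=np.asarray(rows, dtype=float))


IDENTITY = np.eye(5)


def identity_pair(strategy_id: str) -> d.StrategyMatrices:
    return d.StrategyMatrices(
        strategy_id=strategy_id,
        early=make_matrix(strategy_id, "early", IDENTITY),
        late=make_matrix(strategy_id, "late", IDENTITY))


def brute_force_occupancy(occ0, matrices) -> np.ndarray:
    """Independent oracle: sum of path probabilities over all state paths."""
    occ0 = np.asarray(occ0, dtype=float)
    n = len(occ0)
    out = np.zeros(n)
    for start in range(n):
        if occ0[start] == 0:
            continue
        for path in itertools.product(range(n), repeat=len(matrices)):
            weight = occ0[start]
            prev = start
            for matrix, state in zip(matrices, path):
                weight *= matrix[prev, state]
                prev = state
            out[path[-1] if path else start] += weight
    return out
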