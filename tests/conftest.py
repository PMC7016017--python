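import numpy as np
import pytest

import calstores as cs


@pytest.fixture
def tiny_matrix() -> cs.ParalogCountMatrix:
    """2 organisms x 2 families; the hand-evaluated polydomain example."""
    return cs.ParalogCountMatrix(["orgA", "orgB"], ["famX", "famY"], np.array([[4, 1], [0, 1]]))


@pytest.fixture(scope="session")
def planted():
    """4-clade planted matrix at study conditions: 100 organisms x 30
    families, 5x expansions in per-clade family blocks, seed 0."""
    events = cs.planted_block_events(4, 30, multiplier=5.0)
    m, ca, gt = cs.gen_matrix(100, 30, 4, events=events, baseline_rate=1.0, seed=0)
    return m, ca, gt


@pytest.fixture(scope="session")
def core_periphery():
    """Core-periphery graph with a planted 10-clique, seed 0."""
    return cs.gen_core_periphery(seed=0)


def random_matrix(rng: np.random.Generator, n: int, p: int, high: int = 6) -> cs.ParalogCountMatrix:
    counts = rng.integers(0, high, size=(n, p))
    return cs.ParalogCountMatrix(
        [f"o{i}" for i in range(n)], [f"f{j}" for j in range(p)], counts
    )
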