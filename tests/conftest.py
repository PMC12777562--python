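import numpy as np
import pytest

from doorstat import DoorTable, load_fixture


@pytest.fixture(scope="session")
def dori05():
    return load_fixture("dori05_door")


@pytest.fixture(scope="session")
def dori05_components():
    return load_fixture("dori05_components")


def brute_force_pairs(table: DoorTable) -> tuple[float, float, float]:
    """O(n1·n2) win/tie/loss count over expanded per-patient categories.

    Independent of the closed-form cross-tabulation: expands the table to
    one category value per participant and compares every cross-arm pair.
    """
    cats = [
        np.repeat(np.arange(1, table.K + 1), table.counts[i]) for i in range(2)
    ]
    diff = cats[0][:, None] - cats[1][None, :]
    wins = int((diff < 0).sum())  # lower category index = more desirable
    ties = int((diff == 0).sum())
    losses = int((diff > 0).sum())
    return wins, ties, losses


def random_table(rng: np.random.Generator, max_n: int = 50, max_K: int = 8) -> DoorTable:
    """Random 2×K count table with nonempty arms, n ≤ max_n per arm."""
    K = int(rng.integers(2, max_K + 1))
    while True:
        counts = rng.integers(0, max_n // 2 + 1, size=(2, K))
        if counts.sum(axis=1).min() >= 2 and counts.sum(axis=1).max() <= max_n:
            return DoorTable(counts)
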