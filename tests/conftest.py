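"""Shared fixtures: the worked-example distinction table and small datasets."""

import numpy as np
import pytest

from swarmselect import (
    ExpressionDataset,
    SyntheticSpec,
    generate_dataset,
    toy_distinction_table,
)
from swarmselect.distinction import DistinctionTable


@pytest.fixture
def d0() -> DistinctionTable:
    """7-feature, 6-row worked-example table (class sizes 2 and 3)."""
    return toy_distinction_table()


@pytest.fixture
def tiny_dataset() -> ExpressionDataset:
    """3 genes x 4 samples, two classes, hand-enumerable."""
    return ExpressionDataset(
        gene_ids=("g1", "g2", "g3"),
        sample_ids=("s1", "s2", "s3", "s4"),
        values=np.array(
            [
                [1.0, 2.0, 3.0, 4.0],
                [10.0, 0.0, 10.0, 0.0],
                [5.0, 6.0, 7.0, 8.0],
            ]
        ),
        labels=("A", "A", "B", "B"),
    )


@pytest.fixture
def ideal_data():
    """Default planted-structure dataset plus its ground truth."""
    dataset, informative, m = generate_dataset(SyntheticSpec(seed=7))
    return dataset, informative, m


def random_distinction_table(rng) -> DistinctionTable:
    """A random small discernibility matrix with coherent pair structure."""
    n = int(rng.integers(4, 13))
    c1 = int(rng.integers(2, 5))
    c2 = int(rng.integers(2, 5))
    bits = rng.random((c1 * c2, n)) < rng.uniform(0.15, 0.5)
    pairs = tuple((f"a{i}", f"b{j}") for i in range(c1) for j in range(c2))
    return DistinctionTable(
        bits=bits, pair_index=pairs, class_sizes={"A": c1, "B": c2}
    )


def peeling_ranks(objectives) -> list[int]:
    """O(n^2 * maxrank) rank oracle: repeatedly peel the non-dominated set.

    Pure-python and independent of the package's vectorised sort.
    """

    def dom(a, b):
        return a.fit1 >= b.fit1 and a.fit2 >= b.fit2 and (
            a.fit1 > b.fit1 or a.fit2 > b.fit2
        )

    remaining = list(range(len(objectives)))
    ranks = [0] * len(objectives)
    rank = 1
    while remaining:
        front = [
            i
            for i in remaining
            if not any(dom(objectives[j], objectives[i]) for j in remaining if j != i)
        ]
        for i in front:
            ranks[i] = rank
        remaining = [i for i in remaining if i not in set(front)]
        rank += 1
    return ranks


def brute_force_covered(bits: np.ndarray, position) -> int:
    """Row-by-row python loop oracle for the coverage count."""
    sel = [i for i, b in enumerate(position) if b]
    return sum(1 for row in bits if any(row[i] for i in sel))
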