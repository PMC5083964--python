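"""The two feature-subset objectives and their weighted-sum scalarisation.

For a binary position vector v over N retained genes:

    Fit1(v) = (N - O_v) / N          O_v = number of selected genes,
    Fit2(v) = R_v / n_rows           R_v = rows of the distinction table
                                           that v discerns.

Both are maximised: Fit1 rewards small subsets, Fit2 rewards discerning
power, and the two conflict, which is what makes the search multi-objective.
Fit2 equals 1 exactly on reducts (when no all-zero row exists).
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .distinction import DistinctionTable, covered_rows
from .exceptions import DimensionError, ParameterError

__all__ = [
    "ObjectivePair",
    "cardinality",
    "fit1",
    "fit2",
    "evaluate_pair",
    "weighted_fitness",
]


class ObjectivePair(NamedTuple):
    """Both objective values for one candidate subset (each in [0, 1])."""

    fit1: float
    fit2: float


def cardinality(position) -> int:
    """Number of selected features O_v (count of 1 bits)."""
    pos = np.asarray(position)
    if pos.size == 0:
        raise DimensionError("position vector must be nonempty")
    return int(pos.astype(bool).sum())


def fit1(position) -> float:
    """Parsimony objective (N - O_v) / N: 1 for the empty set, 0 for all genes."""
    pos = np.asarray(position)
    n = pos.size
    if n == 0:
        raise DimensionError("position vector must be nonempty")
    return (n - cardinality(pos)) / n


def fit2(position, table: DistinctionTable) -> float:
    """Discerning-power objective R_v / n_rows."""
    return covered_rows(table, position) / table.n_rows


def evaluate_pair(position, table: DistinctionTable) -> ObjectivePair:
    """Evaluate both objectives for one position."""
    return ObjectivePair(fit1(position), fit2(position, table))


def weighted_fitness(pair: ObjectivePair, alpha: float) -> float:
    """Scalarised fitness Fit1 * alpha + Fit2 * (1 - alpha), 0 < alpha < 1.

    Provided so a single-objective (GA-style) search can reuse the same
    objective machinery; the swarm itself optimises the pair directly.
    """
    if not 0.0 < alpha < 1.0:
        raise ParameterError(f"alpha must lie strictly in (0, 1), got {alpha}")
    return pair.fit1 * alpha + pair.fit2 * (1.0 - alpha)
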