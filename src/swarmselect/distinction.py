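"""Distinction (discernibility) tables over inter-class sample pairs.

A row exists for every pair of samples drawn from two different classes;
the entry for a gene is 1 exactly when both samples carry definite (non-*)
and unequal ternary symbols for that gene.  For two classes of sizes C1 and
C2 the table has C1*C2 rows; a feature subset that covers every row (has a
1 in some selected column of each row) is a reduct.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .exceptions import DimensionError, LabelError
from .preprocess import STAR, TernaryTable

__all__ = [
    "DistinctionTable",
    "build_distinction_table",
    "covered_rows",
    "is_reduct",
    "toy_distinction_table",
]


@dataclass
class DistinctionTable:
    """Boolean matrix: rows = inter-class sample pairs, columns = genes."""

    bits: np.ndarray  # bool, n_rows x n_features
    pair_index: tuple[tuple[str, str], ...]
    class_sizes: dict[str, int]
    gene_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)
        if self.bits.ndim != 2:
            raise DimensionError("distinction bits must form a 2-D matrix")
        if len(self.pair_index) != self.bits.shape[0]:
            raise DimensionError("one pair annotation per row is required")
        expected = _expected_rows(self.class_sizes)
        if self.bits.shape[0] != expected:
            raise DimensionError(
                f"{self.bits.shape[0]} rows, but class sizes "
                f"{self.class_sizes} imply {expected}"
            )

    @property
    def n_rows(self) -> int:
        return self.bits.shape[0]

    @property
    def n_features(self) -> int:
        return self.bits.shape[1]

    def to_frame(self):
        """Export as a pandas DataFrame (pairs x genes) for inspection."""
        import pandas as pd

        index = [f"{a}|{b}" for a, b in self.pair_index]
        cols = self.gene_ids or [f"f{i + 1}" for i in range(self.n_features)]
        return pd.DataFrame(self.bits.astype(int), index=index, columns=list(cols))


def _expected_rows(class_sizes: dict[str, int]) -> int:
    sizes = list(class_sizes.values())
    return sum(a * b for a, b in combinations(sizes, 2))


def build_distinction_table(table: TernaryTable, labels) -> DistinctionTable:
    """Build the pair x gene discernibility matrix from a ternary table.

    Rows are ordered lexicographically by (class pair, first-sample index,
    second-sample index) with classes in sorted label order, so repeated
    builds are identical.  Same-class pairs contribute no rows.
    """
    labels = [str(c) for c in labels]
    if len(labels) != table.n_samples:
        raise DimensionError(
            f"{len(labels)} labels for {table.n_samples} samples"
        )
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise LabelError("a distinction table needs at least two classes")
    by_class = {c: [i for i, lab in enumerate(labels) if lab == c] for c in classes}

    sym = table.symbols  # genes x samples
    rows = []
    pairs = []
    sample_ids = table.sample_ids or tuple(f"s{i + 1}" for i in range(table.n_samples))
    for ca, cb in combinations(classes, 2):
        for i in by_class[ca]:
            si = sym[:, i]
            for j in by_class[cb]:
                sj = sym[:, j]
                rows.append((si != sj) & (si != STAR) & (sj != STAR))
                pairs.append((sample_ids[i], sample_ids[j]))
    return DistinctionTable(
        bits=np.array(rows, dtype=bool),
        pair_index=tuple(pairs),
        class_sizes={c: len(by_class[c]) for c in classes},
        gene_ids=table.gene_ids,
    )


def _as_position(position, n_features: int) -> np.ndarray:
    pos = np.asarray(position)
    if pos.ndim != 1 or pos.shape[0] != n_features:
        raise DimensionError(
            f"position length {pos.shape} does not match {n_features} features"
        )
    return pos.astype(bool)


def covered_rows(table: DistinctionTable, position) -> int:
    """Number of rows R_v discerned by the feature subset ``position``.

    A row is discerned when at least one selected column carries a 1 in it.
    """
    sel = _as_position(position, table.n_features)
    if not sel.any():
        return 0
    return int(table.bits[:, sel].any(axis=1).sum())


def is_reduct(table: DistinctionTable, position) -> bool:
    """True when the subset discerns every inter-class pair (covers all rows)."""
    return covered_rows(table, position) == table.n_rows


def toy_distinction_table() -> DistinctionTable:
    """A 7-feature, 6-row worked-example table (classes of sizes 2 and 3).

    The subset v = (1,0,1,1,0,1,1) has cardinality 5 and discerns 5 of the
    6 rows, which makes it a compact fixture for the objective functions.
    """
    rows = [
        "1000000",
        "0100000",
        "0010000",
        "0001010",
        "0000101",
        "1100001",
    ]
    bits = np.array([[ch == "1" for ch in r] for r in rows])
    a_samples = ["C11", "C12"]
    b_samples = ["C21", "C22", "C23"]
    pairs = tuple((a, b) for a in a_samples for b in b_samples)
    return DistinctionTable(
        bits=bits,
        pair_index=pairs,
        class_sizes={"C1": 2, "C2": 3},
        gene_ids=tuple(f"F{i + 1}" for i in range(7)),
    )
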