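"""Normalisation, quartile discretisation and ambiguity filtering.

Each gene (attribute) is min-max normalised to [0, 1] across samples, a
grouped-frequency grid of equal-width intervals is built over its values,
and the first and third quartiles are read off the grid by linear
interpolation within the containing interval.  Values at or below the lower
threshold become ``0`` (under-expressed), values at or above the upper
threshold become ``1`` (over-expressed) and everything in between becomes
the don't-care symbol ``*``.  Genes carrying at least the average number of
don't-cares are discarded as ambiguously expressed.

The grouped-frequency quartile of a grid with interval width ``delta`` is

    Q_k = l_c + ((R_k - cfr_{c-1}) / fr_c) * delta,    R_k = k * N_s / 4,

where ``l_c`` is the lower limit of the interval containing rank ``R_k``,
``fr_c`` its frequency and ``cfr_{c-1}`` the cumulative frequency below it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import (
    DegenerateFilterError,
    EmptyOutputError,
    ParameterError,
    RangeError,
)
from .io import ExpressionDataset

__all__ = [
    "STAR",
    "QuartileGrid",
    "TernaryTable",
    "PreprocessResult",
    "normalize_minmax",
    "build_quartile_grid",
    "partition_value",
    "gene_thresholds",
    "ternarize",
    "filter_ambiguous",
    "preprocess_pipeline",
]

#: Integer code for the don't-care symbol '*' in ternary tables.
STAR: int = 2

_SYMBOL_CHARS = {0: "0", 1: "1", STAR: "*"}


@dataclass
class QuartileGrid:
    """Grouped-frequency grid over [0, 1] for one gene's normalised values."""

    lower_limits: np.ndarray  # l_c, one per interval
    delta: float  # common interval width
    freqs: np.ndarray  # fr_c
    cumfreqs: np.ndarray  # cfr_c
    n_values: int  # N_s

    def __post_init__(self) -> None:
        self.lower_limits = np.asarray(self.lower_limits, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=int)
        self.cumfreqs = np.asarray(self.cumfreqs, dtype=int)
        if self.cumfreqs[-1] != self.n_values:
            raise RangeError("cumulative frequencies do not sum to the value count")


@dataclass
class TernaryTable:
    """Discretised genes x samples table over {0, 1, *}.

    ``kept_gene_indices`` maps each table row back to the gene index in the
    dataset originally fed to the pipeline, so selections can be reported in
    terms of the input gene identifiers.
    """

    symbols: np.ndarray  # int8, genes x samples, values in {0, 1, STAR}
    th_low: np.ndarray  # Th_i per gene
    th_high: np.ndarray  # Th_f per gene
    star_counts: np.ndarray  # '*' count per gene
    kept_gene_indices: np.ndarray  # table row -> original gene index
    gene_ids: tuple[str, ...] = ()
    sample_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.symbols = np.asarray(self.symbols, dtype=np.int8)
        if not np.isin(self.symbols, [0, 1, STAR]).all():
            raise RangeError("ternary symbols must be 0, 1 or *")
        self.th_low = np.asarray(self.th_low, dtype=float)
        self.th_high = np.asarray(self.th_high, dtype=float)
        if np.any(self.th_low > self.th_high + 1e-12):
            raise RangeError("per-gene thresholds must satisfy Th_i <= Th_f")
        self.star_counts = np.asarray(self.star_counts, dtype=int)
        self.kept_gene_indices = np.asarray(self.kept_gene_indices, dtype=int)

    @property
    def n_genes(self) -> int:
        return self.symbols.shape[0]

    @property
    def n_samples(self) -> int:
        return self.symbols.shape[1]

    def symbol_strings(self) -> list[str]:
        """Rows rendered with '0', '1' and '*' characters (for export)."""
        return [
            "".join(_SYMBOL_CHARS[int(s)] for s in row) for row in self.symbols
        ]


@dataclass
class PreprocessResult:
    """Reduced ternary table plus a provenance log of the pipeline run."""

    table: TernaryTable
    dropped_constant_genes: tuple[str, ...]
    removed_ambiguous_genes: tuple[str, ...]
    star_threshold: float | None  # Th_a; None when filtering was bypassed
    n_intervals: int

    def provenance(self) -> dict:
        return {
            "n_intervals": self.n_intervals,
            "dropped_constant_genes": list(self.dropped_constant_genes),
            "removed_ambiguous_genes": list(self.removed_ambiguous_genes),
            "star_threshold": self.star_threshold,
            "thresholds": {
                gid: [float(lo), float(hi)]
                for gid, lo, hi in zip(
                    self.table.gene_ids, self.table.th_low, self.table.th_high
                )
            },
        }


def normalize_minmax(
    dataset: ExpressionDataset,
) -> tuple[ExpressionDataset, tuple[str, ...]]:
    """Min-max normalise each gene to [0, 1] across samples.

    Constant genes (max == min) carry no discriminative signal and cannot be
    scaled, so they are dropped; their identifiers are returned alongside the
    normalised dataset.
    """
    vals = dataset.values
    lo = vals.min(axis=1, keepdims=True)
    hi = vals.max(axis=1, keepdims=True)
    keep = (hi - lo).ravel() > 0
    if not keep.any():
        raise EmptyOutputError("every gene is constant; nothing to normalise")
    dropped = tuple(g for g, k in zip(dataset.gene_ids, keep) if not k)
    scaled = (vals[keep] - lo[keep]) / (hi[keep] - lo[keep])
    norm = ExpressionDataset(
        gene_ids=tuple(g for g, k in zip(dataset.gene_ids, keep) if k),
        sample_ids=dataset.sample_ids,
        values=scaled,
        labels=dataset.labels,
    )
    return norm, dropped


def build_quartile_grid(values, n_intervals: int = 10) -> QuartileGrid:
    """Bin values in [0, 1] into ``n_intervals`` equal-width intervals.

    Interval ``c`` covers ``[l_c, l_c + delta)``; the last interval is closed
    so that a value of exactly 1.0 is counted.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise RangeError("cannot build a grid from no values")
    if n_intervals < 2:
        raise ParameterError("n_intervals must be >= 2")
    if values.min() < 0 or values.max() > 1:
        raise RangeError("grid values must lie in [0, 1]")
    delta = 1.0 / n_intervals
    idx = np.minimum((values / delta).astype(int), n_intervals - 1)
    freqs = np.bincount(idx, minlength=n_intervals)
    return QuartileGrid(
        lower_limits=np.arange(n_intervals) * delta,
        delta=delta,
        freqs=freqs,
        cumfreqs=np.cumsum(freqs),
        n_values=values.size,
    )


def partition_value(grid: QuartileGrid, k: int) -> float:
    """The k-th quartile partition value (k = 1, 2, 3) of a grid.

    The rank of the k-th partition value is ``R_k = k * N_s / 4``; the
    containing interval is the lowest ``c`` with ``cfr_c >= R_k`` (which also
    handles ranks falling on a boundary shared with an empty interval), and
    the value is interpolated linearly within it.
    """
    if k not in (1, 2, 3):
        raise ParameterError("k must be 1, 2 or 3 (four partitions)")
    rank = k * grid.n_values / 4.0
    c = int(np.searchsorted(grid.cumfreqs, rank, side="left"))
    c = min(c, len(grid.freqs) - 1)
    prev = grid.cumfreqs[c - 1] if c > 0 else 0
    if grid.freqs[c] == 0:
        # rank coincides with the boundary of an empty interval
        return float(grid.lower_limits[c])
    return float(grid.lower_limits[c] + ((rank - prev) / grid.freqs[c]) * grid.delta)


def gene_thresholds(values, n_intervals: int = 10) -> tuple[float, float]:
    """Per-gene (Th_i, Th_f) = first and third grouped-frequency quartiles."""
    grid = build_quartile_grid(values, n_intervals)
    return partition_value(grid, 1), partition_value(grid, 3)


def ternarize(
    dataset: ExpressionDataset,
    th_low,
    th_high,
    kept_gene_indices=None,
) -> TernaryTable:
    """Discretise a normalised dataset to {0, 1, *} with per-gene thresholds.

    The rule is applied in order: value <= Th_i gives 0, else value >= Th_f
    gives 1, else '*'.  Testing the lower branch first means a value equal to
    a collapsed threshold (Th_i == Th_f) discretises to 0.
    """
    th_low = np.asarray(th_low, dtype=float).reshape(-1, 1)
    th_high = np.asarray(th_high, dtype=float).reshape(-1, 1)
    if th_low.shape[0] != dataset.n_genes or th_high.shape[0] != dataset.n_genes:
        raise ParameterError("one (Th_i, Th_f) pair per gene is required")
    if np.any(th_low > th_high):
        raise RangeError("thresholds must satisfy Th_i <= Th_f")
    vals = dataset.values
    symbols = np.full(vals.shape, STAR, dtype=np.int8)
    symbols[vals <= th_low] = 0
    symbols[(vals >= th_high) & ~(vals <= th_low)] = 1
    if kept_gene_indices is None:
        kept_gene_indices = np.arange(dataset.n_genes)
    return TernaryTable(
        symbols=symbols,
        th_low=th_low.ravel(),
        th_high=th_high.ravel(),
        star_counts=(symbols == STAR).sum(axis=1),
        kept_gene_indices=kept_gene_indices,
        gene_ids=dataset.gene_ids,
        sample_ids=dataset.sample_ids,
    )


def filter_ambiguous(table: TernaryTable) -> tuple[TernaryTable, float]:
    """Remove genes whose '*' count is at least the average '*' count (Th_a).

    Returns the reduced table and Th_a.  With a single gene the mean equals
    its own count and the comparison is vacuous, so filtering is bypassed.
    """
    if table.n_genes == 1:
        return table, float(table.star_counts.mean())
    th_a = float(table.star_counts.mean())
    keep = table.star_counts < th_a
    if not keep.any():
        raise DegenerateFilterError(
            "ambiguity filtering removed every gene (all '*' counts equal the "
            "mean); try a different n_intervals"
        )
    reduced = TernaryTable(
        symbols=table.symbols[keep],
        th_low=table.th_low[keep],
        th_high=table.th_high[keep],
        star_counts=table.star_counts[keep],
        kept_gene_indices=table.kept_gene_indices[keep],
        gene_ids=tuple(g for g, k in zip(table.gene_ids, keep) if k),
        sample_ids=table.sample_ids,
    )
    return reduced, th_a


def preprocess_pipeline(
    dataset: ExpressionDataset, n_intervals: int = 10
) -> PreprocessResult:
    """Normalise, discretise and filter a raw dataset into a reduced table.

    Stages: min-max normalisation (dropping constant genes); per-gene
    quartile grid; Th_i / Th_f from partition values k = 1 and k = 3;
    ternarisation; removal of ambiguously expressed genes.
    """
    norm, dropped = normalize_minmax(dataset)
    surviving_norm = set(norm.gene_ids)
    kept_idx = np.array(
        [i for i, g in enumerate(dataset.gene_ids) if g in surviving_norm]
    )
    th_low = np.empty(norm.n_genes)
    th_high = np.empty(norm.n_genes)
    for g in range(norm.n_genes):
        th_low[g], th_high[g] = gene_thresholds(norm.values[g], n_intervals)
    table = ternarize(norm, th_low, th_high, kept_gene_indices=kept_idx)
    before = table.gene_ids
    if table.n_genes > 1:
        table, th_a = filter_ambiguous(table)
    else:
        th_a = None
    surviving = set(table.gene_ids)
    removed = tuple(g for g in before if g not in surviving)
    return PreprocessResult(
        table=table,
        dropped_constant_genes=dropped,
        removed_ambiguous_genes=removed,
        star_threshold=th_a,
        n_intervals=n_intervals,
    )
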