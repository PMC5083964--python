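"""Reading expression matrices and writing selection reports.

The on-disk dialect is deliberately small: a delimited matrix whose first
column holds gene identifiers and whose header row holds sample identifiers
(genes in rows), or its transpose (samples in rows).  Class labels come from
a two-column ``sample_id,label`` file or from a designated row of the matrix
itself.  Anything fancier (CDT, RES, CEL) is expected to be converted to
CSV/TSV first.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import DimensionError, DuplicateIdError, LabelError, ParseError

__all__ = [
    "ExpressionDataset",
    "read_expression_table",
    "read_label_file",
    "write_selection_report",
    "read_selection_report",
]


@dataclass
class ExpressionDataset:
    """A genes x samples real-valued expression matrix with per-sample labels.

    Attributes
    ----------
    gene_ids
        Unique gene (attribute) identifiers, one per matrix row.
    sample_ids
        Unique sample (object) identifiers, one per matrix column.
    values
        Float matrix of shape ``(len(gene_ids), len(sample_ids))``.
    labels
        One class label per sample, aligned with ``sample_ids``.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.gene_ids = tuple(str(g) for g in self.gene_ids)
        self.sample_ids = tuple(str(s) for s in self.sample_ids)
        self.labels = tuple(str(c) for c in self.labels)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ParseError("expression values must form a 2-D matrix")
        n_genes, n_samples = self.values.shape
        if n_genes != len(self.gene_ids):
            raise ParseError(
                f"matrix has {n_genes} rows but {len(self.gene_ids)} gene ids"
            )
        if n_samples != len(self.sample_ids):
            raise ParseError(
                f"matrix has {n_samples} columns but {len(self.sample_ids)} sample ids"
            )
        if len(self.labels) != n_samples:
            raise LabelError(
                f"{len(self.labels)} labels for {n_samples} samples"
            )
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                seen: set[str] = set()
                dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
                raise DuplicateIdError(f"duplicate {name} id: {dup!r}")
        if not np.all(np.isfinite(self.values)):
            r, c = np.argwhere(~np.isfinite(self.values))[0]
            raise ParseError(
                f"non-finite value at gene {self.gene_ids[r]!r}, "
                f"sample {self.sample_ids[c]!r} (missing values are not supported)"
            )

    # -- derived views ---------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def class_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for c in self.labels:
            sizes[c] = sizes.get(c, 0) + 1
        return sizes

    def validate_for_selection(self) -> None:
        """Require >= 2 classes and >= 2 samples in each class."""
        sizes = self.class_sizes()
        if len(sizes) < 2:
            raise LabelError("feature selection needs at least 2 classes")
        small = [c for c, n in sizes.items() if n < 2]
        if small:
            raise LabelError(
                f"each class needs at least 2 samples; too small: {small}"
            )

    def equals(self, other: "ExpressionDataset") -> bool:
        return (
            self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and self.labels == other.labels
            and np.array_equal(self.values, other.values)
        )


def _infer_sep(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_label_file(path: str | Path, sep: str | None = None) -> dict[str, str]:
    """Read a two-column ``sample_id,label`` file into a mapping.

    A header row reading ``sample_id,label`` (or ``sample,label``) is
    tolerated and skipped.
    """
    path = Path(path)
    delim = _infer_sep(path, sep)
    mapping: dict[str, str] = {}
    with open(path, newline="") as fh:
        for row_no, row in enumerate(csv.reader(fh, delimiter=delim)):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise LabelError(
                    f"{path}: line {row_no + 1} does not have two columns"
                )
            sid, lab = row[0].strip(), row[1].strip()
            if row_no == 0 and sid.lower() in {"sample", "sample_id", "id"}:
                continue
            if sid in mapping:
                raise DuplicateIdError(f"duplicate sample id in label file: {sid!r}")
            mapping[sid] = lab
    return mapping


def read_expression_table(
    path: str | Path,
    orientation: str = "genes",
    label_file: str | Path | None = None,
    label_row: str | None = None,
    sep: str | None = None,
) -> ExpressionDataset:
    """Read a delimited expression matrix plus labels into a dataset.

    Parameters
    ----------
    path
        CSV/TSV file.  First column = row identifiers, header = column
        identifiers.  The delimiter is taken from the extension (``.tsv`` /
        ``.tab`` / ``.txt`` means tab) unless ``sep`` overrides it.
    orientation
        ``"genes"`` if genes are in rows (the default microarray layout) or
        ``"samples"`` if samples are in rows; the matrix is transposed to the
        internal genes x samples layout.
    label_file
        Two-column ``sample_id,label`` file.  Exactly one of ``label_file``
        and ``label_row`` must be given.
    label_row
        Name of a matrix row (after orientation normalisation) holding one
        class label per sample; the row is removed from the gene set.
    """
    if orientation not in {"genes", "samples"}:
        raise ParseError(f"orientation must be 'genes' or 'samples', got {orientation!r}")
    if (label_file is None) == (label_row is None):
        raise LabelError("provide exactly one of label_file or label_row")

    path = Path(path)
    delim = _infer_sep(path, sep)
    df = pd.read_csv(path, sep=delim, index_col=0, header=0, dtype=str)
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    if orientation == "samples":
        df = df.T

    labels_series: pd.Series | None = None
    if label_row is not None:
        if label_row not in df.index:
            raise LabelError(f"label row {label_row!r} not found in {path}")
        labels_series = df.loc[label_row].astype(str).str.strip()
        df = df.drop(index=label_row)

    gene_ids = tuple(df.index)
    sample_ids = tuple(df.columns)

    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().to_numpy() | df.isna().to_numpy()
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ParseError(
            f"{path}: non-numeric or missing value at row {gene_ids[r]!r}, "
            f"column {sample_ids[c]!r}"
        )

    if label_file is not None:
        mapping = read_label_file(label_file, sep=sep)
        missing = [s for s in sample_ids if s not in mapping]
        if missing:
            raise LabelError(f"no label for sample(s): {missing}")
        labels = tuple(mapping[s] for s in sample_ids)
    else:
        assert labels_series is not None
        labels = tuple(labels_series.loc[list(sample_ids)])

    return ExpressionDataset(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        values=numeric.to_numpy(dtype=float),
        labels=labels,
    )


# -- selection reports ---------------------------------------------------


def _bits_to_string(position: Iterable[int]) -> str:
    return "".join("1" if int(b) else "0" for b in position)


def write_selection_report(
    archive,
    gene_ids: Sequence[str],
    path: str | Path,
    meta: Mapping | None = None,
) -> tuple[Path, Path]:
    """Write a Pareto archive as JSON plus a flat per-gene CSV.

    The JSON lists, per archived solution: the bitstring over the retained
    genes, the selected gene identifiers, both objective values and the
    cardinality.  The companion CSV (``<stem>.genes.csv``) has one row per
    (solution, gene) pair.  Returns ``(json_path, csv_path)``.
    """
    path = Path(path)
    solutions = []
    for member in archive.members:
        bits = np.asarray(member.position, dtype=int)
        if len(bits) != len(gene_ids):
            raise DimensionError(
                f"archive position length {len(bits)} does not match "
                f"{len(gene_ids)} gene ids"
            )
        genes = [gene_ids[i] for i in np.flatnonzero(bits)]
        solutions.append(
            {
                "bits": _bits_to_string(bits),
                "genes": genes,
                "fit1": float(member.objectives.fit1),
                "fit2": float(member.objectives.fit2),
                "cardinality": int(bits.sum()),
                "generation": int(member.generation),
            }
        )
    payload = {"solutions": solutions, "meta": dict(meta or {})}
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")

    csv_path = path.with_name(path.stem + ".genes.csv")
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["solution", "gene", "fit1", "fit2", "cardinality"])
        for i, sol in enumerate(solutions):
            for g in sol["genes"]:
                writer.writerow([i, g, sol["fit1"], sol["fit2"], sol["cardinality"]])
    return path, csv_path


def read_selection_report(path: str | Path) -> dict:
    """Re-parse a JSON selection report written by :func:`write_selection_report`."""
    with open(path) as fh:
        return json.load(fh)
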