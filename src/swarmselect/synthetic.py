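"""Two-class synthetic expression matrices with a planted minimal reduct.

The generator emulates the structure the selection pipeline assumes: a
handful of informative genes that separate the two classes, buried among
uniform-noise genes.  Class-B samples are partitioned into ``cover_size``
blocks and informative gene i is expressed high exactly in block i (and low
in class A and the other blocks), so gene i discerns exactly the
A x block_i sample pairs and the planted minimal covering subset has size
exactly ``cover_size`` — a ground truth tests can check against without
re-deriving it from data.

In ideal mode the low/high expression states are the extreme points 0.0 and
1.0 of the intensity scale.  This makes the planted structure provable:
whatever per-gene quartile thresholds the preprocessing derives, a low
value (0.0) can never exceed Th_i and a high value (1.0) can never fall
below Th_f, so informative genes always discretise to definite symbols with
zero don't-cares.  Noisy mode perturbs every entry with Gaussian noise and
clips to [0, 1], restoring a continuous spread.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConstructionError
from .io import ExpressionDataset

__all__ = ["SyntheticSpec", "generate_dataset", "planted_cover_size"]

_LOW = 0.0
_HIGH = 1.0


@dataclass
class SyntheticSpec:
    """Parameters of a planted-structure two-class dataset.

    Defaults describe a small but nontrivial instance: 30 genes of which 3
    are informative, a planted minimal cover of size 3, and classes of 5
    and 6 samples (microarray-scale class sizes).
    """

    n_genes: int = 30
    n_informative: int = 3
    cover_size: int = 3
    class_sizes: tuple[int, int] = (5, 6)
    mode: str = "ideal"
    noise_sd: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_informative > self.n_genes:
            problems.append("n_informative cannot exceed n_genes")
        if not 1 <= self.cover_size <= self.n_informative:
            problems.append("cover_size must lie in [1, n_informative]")
        a, b = self.class_sizes
        if a < 2 or b < 2:
            problems.append("each class needs at least 2 samples")
        if b < self.cover_size:
            problems.append(
                f"class B has {b} samples but {self.cover_size} blocks are needed"
            )
        if self.mode not in {"ideal", "noisy"}:
            problems.append(f"mode must be 'ideal' or 'noisy', got {self.mode!r}")
        if self.noise_sd < 0:
            problems.append("noise_sd must be >= 0")
        if problems:
            raise ConstructionError("; ".join(problems))


def planted_cover_size(spec: SyntheticSpec) -> int:
    """Size of the planted minimal covering subset (ground truth for tests)."""
    spec.validate()
    return spec.cover_size


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[ExpressionDataset, tuple[str, ...], int]:
    """Generate the dataset; returns (dataset, informative gene ids, m).

    Class-B samples are assigned to blocks round-robin; informative gene i
    (and any duplicate informative gene beyond the first m, which reuses
    block i mod m) is high in block i and low elsewhere.  Noise genes draw
    uniformly on [0, 1].  Gene order is shuffled so informative genes are
    not positionally obvious; everything is reproducible from the seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    a, b = spec.class_sizes
    n_samples = a + b
    m = spec.cover_size

    values = np.empty((spec.n_genes, n_samples))
    block_of_b = np.arange(b) % m  # round-robin block assignment

    for g in range(spec.n_informative):
        block = g % m
        row = np.full(n_samples, _LOW)
        row[a + np.flatnonzero(block_of_b == block)] = _HIGH
        values[g] = row
    values[spec.n_informative:] = rng.uniform(
        0.0, 1.0, size=(spec.n_genes - spec.n_informative, n_samples)
    )

    if spec.mode == "noisy":
        values = np.clip(
            values + rng.normal(0.0, spec.noise_sd, size=values.shape), 0.0, 1.0
        )

    order = rng.permutation(spec.n_genes)
    values = values[order]
    width = len(str(spec.n_genes))
    gene_ids = tuple(f"g{i + 1:0{width}d}" for i in range(spec.n_genes))
    informative = tuple(
        gene_ids[int(np.flatnonzero(order == g)[0])]
        for g in range(spec.n_informative)
    )

    dataset = ExpressionDataset(
        gene_ids=gene_ids,
        sample_ids=tuple(f"s{i + 1:02d}" for i in range(n_samples)),
        values=values,
        labels=tuple(["A"] * a + ["B"] * b),
    )
    return dataset, informative, m
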