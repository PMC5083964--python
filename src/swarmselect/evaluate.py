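"""Validation of selected gene subsets: k-NN cross-validation and z-scores.

k-NN with Euclidean distance on the selected genes is the native
reference classifier (k odd to avoid voting ties).  Any object following
the fit/predict protocol (e.g. a scikit-learn estimator) can be plugged in
for external validation through the same cross-validation driver.

Z-scores standardise a gene's intensity against all genes on the same
array: z = (G_i - mu) / sigma with mu and sigma (population SD) computed
per sample across every gene, so highly positive z marks genes expressed
far above the array-wide aggregate.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .exceptions import (
    DegenerateSampleError,
    DimensionError,
    ParameterError,
    StratificationError,
)
from .io import ExpressionDataset

__all__ = [
    "EvaluationReport",
    "ZScoreReport",
    "knn_predict",
    "stratified_folds",
    "cross_validate",
    "z_scores",
    "sklearn_classifier",
]


@dataclass
class EvaluationReport:
    classifier: str
    k: int | None
    folds: int
    fold_accuracies: tuple[float, ...]  # percent per held-out fold
    mean_accuracy: float  # percent
    subset_gene_ids: tuple[str, ...]
    seed: int

    def to_dict(self) -> dict:
        return {
            "classifier": self.classifier,
            "k": self.k,
            "folds": self.folds,
            "fold_accuracies": [round(a, 2) for a in self.fold_accuracies],
            "mean_accuracy": round(self.mean_accuracy, 2),
            "subset_gene_ids": list(self.subset_gene_ids),
            "seed": self.seed,
        }


@dataclass
class ZScoreReport:
    """Per-(selected gene, sample) z values plus per-sample mu and sigma.

    Standardisation axis: within each sample, across ALL genes, with the
    population (divide-by-n) standard deviation.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    z: np.ndarray  # selected genes x samples
    mu: np.ndarray  # per sample
    sigma: np.ndarray  # per sample

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.z, index=list(self.gene_ids), columns=list(self.sample_ids))


def knn_predict(train_matrix, train_labels, query, k: int):
    """Majority label among the k nearest training samples (Euclidean).

    Distance ties are broken by training order (stable sort); a majority
    tie between labels goes to the label of the nearest sample voting for
    one of the tied labels.  k must be odd.
    """
    train_matrix = np.asarray(train_matrix, dtype=float)
    query = np.asarray(query, dtype=float)
    train_labels = list(train_labels)
    if train_matrix.ndim != 2 or train_matrix.shape[0] == 0:
        raise ParameterError("training set must be a nonempty samples x genes matrix")
    if len(train_labels) != train_matrix.shape[0]:
        raise DimensionError("one label per training sample is required")
    if query.shape != (train_matrix.shape[1],):
        raise DimensionError("query dimension does not match training matrix")
    if k < 1 or k % 2 == 0:
        raise ParameterError(f"k must be an odd positive integer, got {k}")
    if k > train_matrix.shape[0]:
        raise ParameterError(f"k={k} exceeds the {train_matrix.shape[0]} training samples")

    dist = np.sqrt(((train_matrix - query) ** 2).sum(axis=1))
    order = np.argsort(dist, kind="stable")[:k]
    votes = [train_labels[i] for i in order]
    counts = Counter(votes)
    top = max(counts.values())
    tied = {lab for lab, c in counts.items() if c == top}
    for lab in votes:  # nearest-first resolution of label ties
        if lab in tied:
            return lab
    raise AssertionError("unreachable")


def stratified_folds(labels, folds: int, rng) -> np.ndarray:
    """Assign each sample to a fold, stratified by class.

    Within each class the samples are shuffled and dealt round-robin, so
    fold sizes within a class differ by at most one.  Returns an integer
    fold id per sample.
    """
    labels = [str(c) for c in labels]
    if folds < 2:
        raise ParameterError("need at least 2 folds")
    counts = Counter(labels)
    small = {c: n for c, n in counts.items() if n < folds}
    if small:
        raise StratificationError(
            f"classes smaller than the fold count {folds}: {small}; "
            "reduce the number of folds"
        )
    assignment = np.empty(len(labels), dtype=int)
    for c in sorted(counts):
        idx = np.array([i for i, lab in enumerate(labels) if lab == c])
        perm = rng.permutation(idx)
        assignment[perm] = np.arange(perm.size) % folds
    return assignment


def cross_validate(
    dataset: ExpressionDataset,
    subset,
    classifier="knn",
    *,
    k: int = 1,
    folds: int = 10,
    seed: int = 0,
) -> EvaluationReport:
    """Stratified k-fold cross-validation of a gene subset.

    ``subset`` is a bit vector over the dataset's genes.  ``classifier`` is
    either the string ``"knn"`` (native k-NN with parameter ``k``) or any
    object exposing ``fit(X, y)`` / ``predict(X)``.
    """
    subset = np.asarray(subset).astype(bool)
    if subset.shape != (dataset.n_genes,):
        raise DimensionError(
            f"subset length {subset.size} does not match {dataset.n_genes} genes"
        )
    if not subset.any():
        raise ParameterError("the evaluated subset selects no genes")
    x = dataset.values[subset].T  # samples x selected genes
    y = np.array(dataset.labels)
    rng = np.random.default_rng(seed)
    assignment = stratified_folds(dataset.labels, folds, rng)

    accuracies = []
    for f in range(folds):
        test = assignment == f
        train = ~test
        if classifier == "knn":
            preds = [
                knn_predict(x[train], y[train], q, k=k) for q in x[test]
            ]
        else:
            classifier.fit(x[train], y[train])
            preds = list(classifier.predict(x[test]))
        correct = sum(p == t for p, t in zip(preds, y[test]))
        accuracies.append(100.0 * correct / max(test.sum(), 1) if test.any() else 100.0)

    name = "knn" if classifier == "knn" else type(classifier).__name__
    return EvaluationReport(
        classifier=name,
        k=k if classifier == "knn" else None,
        folds=folds,
        fold_accuracies=tuple(accuracies),
        mean_accuracy=float(np.mean(accuracies)),
        subset_gene_ids=tuple(
            g for g, s in zip(dataset.gene_ids, subset) if s
        ),
        seed=seed,
    )


def z_scores(dataset: ExpressionDataset, subset) -> ZScoreReport:
    """Z-scores of the selected genes within each sample.

    mu and sigma are computed per sample over ALL genes of the dataset
    (population SD); z is reported only for the selected genes, in gene
    order.
    """
    if dataset.n_genes < 2:
        raise ParameterError("z-scores need at least 2 genes per sample")
    subset = np.asarray(subset).astype(bool)
    if subset.shape != (dataset.n_genes,):
        raise DimensionError(
            f"subset length {subset.size} does not match {dataset.n_genes} genes"
        )
    mu = dataset.values.mean(axis=0)
    sigma = dataset.values.std(axis=0)  # population SD (ddof=0)
    flat = np.flatnonzero(sigma == 0)
    if flat.size:
        raise DegenerateSampleError(
            f"sample {dataset.sample_ids[flat[0]]!r} has zero intensity variance"
        )
    z = (dataset.values[subset] - mu) / sigma
    return ZScoreReport(
        gene_ids=tuple(g for g, s in zip(dataset.gene_ids, subset) if s),
        sample_ids=dataset.sample_ids,
        z=z,
        mu=mu,
        sigma=sigma,
    )


_SKLEARN_CLASSIFIERS = {
    "naive_bayes": ("sklearn.naive_bayes", "GaussianNB", {}),
    "logistic": ("sklearn.linear_model", "LogisticRegression", {"max_iter": 1000}),
    "svm": ("sklearn.svm", "SVC", {}),
    "decision_tree": ("sklearn.tree", "DecisionTreeClassifier", {"random_state": 0}),
    "random_forest": ("sklearn.ensemble", "RandomForestClassifier", {"random_state": 0}),
}


def sklearn_classifier(name: str):
    """Instantiate a named scikit-learn classifier for external validation.

    These are convenience adapters only — the native method is k-NN; the
    external families exist to sanity-check subsets with independent
    learners.
    """
    try:
        module_name, cls_name, kwargs = _SKLEARN_CLASSIFIERS[name]
    except KeyError:
        raise ParameterError(
            f"unknown classifier {name!r}; choose from "
            f"{sorted(_SKLEARN_CLASSIFIERS)} or 'knn'"
        ) from None
    import importlib

    module = importlib.import_module(module_name)
    return getattr(module, cls_name)(**kwargs)
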