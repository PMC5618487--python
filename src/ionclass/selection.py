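"""ANOVA F-value feature ranking and incremental feature selection (IFS).

Each feature is scored by the one-way ANOVA F statistic

    F = MSB / MSW,
    MSB = sum_i n_i (mean_i - grand_mean)^2 / (K - 1),
    MSW = sum_i sum_j (x_ij - mean_i)^2 / (N - K),

over the K class groups. Features that separate the training classes
perfectly (MSW = 0, MSB > 0) receive +inf and sort first; features with no
between-class signal get 0. Ties break by ascending original feature index so
the ranking is deterministic.

IFS then walks prefixes of the ranked list: the classifier is evaluated on
the top-k features for k = 1..M and the smallest k attaining the maximum
overall accuracy wins. The evaluator is injected, so the search is agnostic
to the classifier (tests can use a cheap one; the production choice is
jackknife SVM accuracy with fixed hyperparameters).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence, Union

import numpy as np
import pandas as pd

PathLike = Union[str, Path]


@dataclass(frozen=True)
class LabeledDataset:
    """A feature matrix with one class label per row.

    Invariants checked at construction: at least two classes, every class
    with at least two samples (within-group variance and leave-one-out both
    need them), label count equal to row count.
    """

    matrix: pd.DataFrame
    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        object.__setattr__(self, "labels", labels)
        if len(labels) != len(self.matrix):
            raise ValueError("one label per matrix row required")
        classes, counts = np.unique(labels, return_counts=True)
        if len(classes) < 2:
            raise ValueError("need at least two classes")
        if counts.min() < 2:
            small = classes[counts.argmin()]
            raise ValueError(f"class {small!r} has fewer than 2 samples")

    @property
    def n_samples(self) -> int:
        return len(self.matrix)

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def feature_names(self) -> list[str]:
        return list(self.matrix.columns)

    def select(self, features: Sequence[str]) -> "LabeledDataset":
        """Restrict to the given feature columns (order preserved)."""
        return LabeledDataset(self.matrix[list(features)], self.labels)


@dataclass(frozen=True)
class FeatureRanking:
    """Per-feature F values plus the induced order (best first)."""

    feature_names: tuple[str, ...]
    f_values: np.ndarray
    order: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        f = np.asarray(self.f_values, dtype=float)
        if len(f) != len(self.feature_names):
            raise ValueError("one F value per feature required")
        # descending F, +inf first, ties by ascending original index
        order = np.lexsort((np.arange(len(f)), -f))
        object.__setattr__(self, "f_values", f)
        object.__setattr__(self, "order", order)

    def ranked_names(self) -> list[str]:
        return [self.feature_names[i] for i in self.order]

    def to_tsv(self, path: PathLike) -> None:
        frame = pd.DataFrame(
            {
                "feature": self.ranked_names(),
                "f_value": self.f_values[self.order],
                "rank": np.arange(1, len(self.order) + 1),
            }
        )
        frame.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class IFSResult:
    """Accuracy-vs-k curve of incremental feature selection and its optimum."""

    accuracy_curve: tuple[tuple[int, float], ...]
    best_k: int
    best_accuracy: float
    selected_features: tuple[str, ...]

    def to_tsv(self, path: PathLike) -> None:
        frame = pd.DataFrame(self.accuracy_curve, columns=["k", "overall_accuracy"])
        frame.to_csv(path, sep="\t", index=False)


def _group_stats(x: np.ndarray, groups: list[np.ndarray]):
    n = np.array([g.size for g in groups], dtype=float)
    means = np.array([x[g].mean(axis=0) for g in groups])
    return n, means


def anova_f_all(dataset: LabeledDataset) -> np.ndarray:
    """Vectorized one-way ANOVA F for every feature column.

    Returns +inf where MSW == 0 and MSB > 0, and 0 where MSB == 0 (a warning
    is emitted for features constant across all samples, which carry no
    signal at all).
    """
    x = dataset.matrix.to_numpy(dtype=float)
    labels = dataset.labels
    classes = dataset.classes
    groups = [np.flatnonzero(labels == c) for c in classes]
    n_i, means = _group_stats(x, groups)
    grand = x.mean(axis=0)
    k, n = len(classes), len(labels)

    msb = (n_i[:, None] * (means - grand) ** 2).sum(axis=0) / (k - 1)
    ssw = np.zeros(x.shape[1])
    for g, m in zip(groups, means):
        ssw += ((x[g] - m) ** 2).sum(axis=0)
    msw = ssw / (n - k)

    tol = 1e-12 * max(1.0, float(np.abs(x).max(initial=0.0)) ** 2)
    msb_zero = msb <= tol
    msw_zero = msw <= tol
    both_zero = msb_zero & msw_zero
    if both_zero.any():
        names = [dataset.feature_names[i] for i in np.flatnonzero(both_zero)[:5]]
        warnings.warn(
            f"{int(both_zero.sum())} feature(s) constant across all samples "
            f"(uninformative), e.g. {names}; F set to 0",
            stacklevel=2,
        )
    f = np.empty(x.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        f = msb / msw
    f[msw_zero & ~msb_zero] = np.inf
    f[msb_zero] = 0.0
    return f


def anova_f(dataset: LabeledDataset, feature_index: int) -> float:
    """One-way ANOVA F for a single feature column (see :func:`anova_f_all`)."""
    sub = LabeledDataset(dataset.matrix.iloc[:, [feature_index]], dataset.labels)
    return float(anova_f_all(sub)[0])


def rank_features(dataset: LabeledDataset) -> FeatureRanking:
    """Score every feature with ANOVA F and rank best-first."""
    return FeatureRanking(
        feature_names=tuple(dataset.feature_names),
        f_values=anova_f_all(dataset),
    )


Evaluator = Callable[[LabeledDataset], float]


def ifs_search(
    dataset: LabeledDataset,
    ranking: FeatureRanking,
    evaluator: Evaluator,
    stride: int = 1,
) -> IFSResult:
    """Incremental feature selection over prefixes of the ranked feature list.

    Evaluates the injected ``evaluator`` (mapping a feature-subset dataset to
    overall accuracy) on the top-k features for k = 1, 1+stride, ... and
    always at k = M. Returns the full curve and the smallest k attaining the
    maximum accuracy. ``stride`` exists purely for speed; the default 1
    evaluates every prefix.
    """
    if set(ranking.feature_names) != set(dataset.feature_names):
        raise ValueError("ranking does not cover the dataset's features")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    ranked = ranking.ranked_names()
    total = len(ranked)
    ks = list(range(1, total + 1, stride))
    if ks[-1] != total:
        ks.append(total)
    curve: list[tuple[int, float]] = []
    for k in ks:
        subset = dataset.select(ranked[:k])
        try:
            accuracy = float(evaluator(subset))
        except Exception as err:
            raise RuntimeError(f"IFS evaluator failed at k={k}: {err}") from err
        curve.append((k, accuracy))
    best_k, best_accuracy = max(curve, key=lambda ka: (ka[1], -ka[0]))
    return IFSResult(
        accuracy_curve=tuple(curve),
        best_k=best_k,
        best_accuracy=best_accuracy,
        selected_features=tuple(ranked[:best_k]),
    )
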