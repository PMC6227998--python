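"""Single-feature discriminant classification of colony feature vectors.

Because the image sets are small (tens of images per group), a full
multivariate classifier on the M + 3 augmented features would overfit
badly.  Instead, a linear discriminant is fitted on exactly ONE
coordinate at a time; the coordinate with the best score is selected by
exhaustive search.  With uniform class priors and a pooled (equal)
within-class variance, the one-dimensional linear discriminant reduces
to nearest-class-mean assignment, which is how it is computed here.

Three evaluation protocols are provided:

* ``repeated_evaluation`` — n repeats of a random, group-stratified
  even train/test split (odd group sizes put the extra image in
  training, e.g. 9 -> 5 train + 4 test), with CSPs refitted on the
  training images of each repeat; reports the mean and (sample)
  standard deviation of the test accuracy and how often each spatial
  index was among the tied-best features.
* ``loocv_evaluate`` — leave-one-out cross-validation, with the CSP
  model and the feature selection redone on every fold of S - 1 images
  so the held-out image never influences the centres.
* ``feature_analysis`` — a single split in which every feature's test
  score is recorded, exposing which CSPs (and hence which local shape
  patterns) discriminate between the groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .features import (
    CSPModel,
    SPATIAL_FEATURE_NAMES,
    assign_csp_labels,
    augment_features,
    csp_histogram,
    fit_csp_model,
)
from .indices import SpatialIndexSet

logger = logging.getLogger(__name__)

__all__ = [
    "ImageData",
    "SingleFeatureLDA",
    "ExperimentResult",
    "fit_single_feature_lda",
    "select_best_feature",
    "train_test_evaluate",
    "repeated_evaluation",
    "loocv_evaluate",
    "feature_analysis",
    "split_train_test",
    "feature_names",
]


@dataclass(frozen=True)
class ImageData:
    """Precomputed per-image inputs to classification.

    Shape primitives and spatial indices depend only on the image, so
    they are computed once; clustering and feature selection, which
    depend on the train/test split, are redone per evaluation run.
    """

    image_id: str
    group: str
    primitives_um: np.ndarray  # (N_boundary, D)
    indices: SpatialIndexSet


@dataclass(frozen=True)
class SingleFeatureLDA:
    """Equal-variance Gaussian discriminant on one feature coordinate."""

    feature_index: int
    class_order: tuple[str, ...]
    class_means: np.ndarray
    pooled_var: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Class label per value: the nearest class mean.

        With uniform priors and one shared variance the discriminant
        score ordering equals the (negative) squared distance to the
        class mean, so the pooled variance does not affect the argmax;
        ties go to the earliest class in ``class_order``.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        d2 = (x[:, None] - self.class_means[None, :]) ** 2
        idx = np.argmin(d2, axis=1)
        return np.array([self.class_order[i] for i in idx])

    def accuracy(self, x: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.predict(x) == np.asarray(y)))


@dataclass(frozen=True)
class ExperimentResult:
    """Accuracies and feature-selection bookkeeping for one protocol."""

    protocol: str
    n_runs: int
    accuracies: np.ndarray
    mean_accuracy: float
    sd_accuracy: float
    index_counts: dict[str, int]
    feature_space_size: int
    S: int | None = None
    best_features: list[int] = field(default_factory=list)
    perfect_features: list[tuple[int, str]] = field(default_factory=list)
    perfect_centres: dict[int, list[float]] = field(default_factory=dict)
    best_score: float | None = None


def _class_order(y: np.ndarray) -> tuple[str, ...]:
    seen: dict[str, None] = {}
    for label in y:
        seen.setdefault(label, None)
    return tuple(seen.keys())


def fit_single_feature_lda(
    X: np.ndarray, y: np.ndarray, j: int
) -> SingleFeatureLDA:
    """Fit the one-feature discriminant on coordinate j of X."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    order = _class_order(y)
    if len(order) < 2:
        raise ValueError("need at least two classes to fit a discriminant")
    x = X[:, j]
    means = np.array([x[y == c].mean() for c in order])
    ss = sum(float(((x[y == c] - mu) ** 2).sum()) for c, mu in zip(order, means))
    dof = x.size - len(order)
    pooled = ss / dof if dof > 0 else 0.0
    if np.allclose(means, means[0]):
        logger.debug("feature %d: all class means identical", j)
    return SingleFeatureLDA(
        feature_index=j,
        class_order=order,
        class_means=means,
        pooled_var=pooled,
    )


def _training_margin(clf: SingleFeatureLDA) -> float:
    """Standardized separation of the closest pair of class means.

    Used as a secondary ranking when several features tie on accuracy:
    on small training sets many features saturate at perfect training
    accuracy, and of those, the one whose class means sit furthest
    apart relative to the pooled spread generalizes best.
    """
    means = np.sort(clf.class_means)
    gap = float(np.diff(means).min()) if means.size > 1 else 0.0
    sd = float(np.sqrt(clf.pooled_var))
    if sd == 0.0:
        return np.inf if gap > 0 else 0.0
    return gap / sd


def select_best_feature(
    X: np.ndarray,
    y: np.ndarray,
    X_score: np.ndarray | None = None,
    y_score: np.ndarray | None = None,
) -> tuple[int, SingleFeatureLDA, list[int]]:
    """Exhaustively score every coordinate; return the best.

    Classifiers are always fitted on (X, y).  By default the selection
    score is the training accuracy on the same data; passing
    (X_score, y_score) scores on held-out data instead.  Returns the
    winning index, its fitted classifier, and the full accuracy-tied
    index list.  Among accuracy ties the feature with the largest
    training margin wins; any remaining tie goes to the smallest index.
    """
    if X_score is None:
        X_score, y_score = X, y
    accs = np.empty(X.shape[1])
    clfs = []
    for j in range(X.shape[1]):
        clf = fit_single_feature_lda(X, y, j)
        clfs.append(clf)
        accs[j] = clf.accuracy(X_score[:, j], y_score)
    best = float(accs.max())
    tied = [int(j) for j in np.nonzero(np.isclose(accs, best))[0]]
    winner = max(tied, key=lambda j: (_training_margin(clfs[j]), -j))
    return winner, clfs[winner], tied


def feature_names(model: CSPModel) -> list[str]:
    return [f"CSP_{i + 1}" for i in range(model.M)] + list(SPATIAL_FEATURE_NAMES)


def split_train_test(
    data: list[ImageData], rng: np.random.Generator
) -> tuple[list[int], list[int]]:
    """Group-stratified random even split; odd groups favour training.

    A group of size S_g contributes ceil(S_g / 2) training images, so a
    9-image group splits 5 train / 4 test.
    """
    groups = _class_order(np.array([d.group for d in data]))
    train: list[int] = []
    test: list[int] = []
    for g in groups:
        idx = [i for i, d in enumerate(data) if d.group == g]
        if len(idx) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 images")
        perm = rng.permutation(len(idx))
        n_train = (len(idx) + 1) // 2
        train.extend(idx[i] for i in perm[:n_train])
        test.extend(idx[i] for i in perm[n_train:])
    return sorted(train), sorted(test)


def _build_features(
    data: list[ImageData], train_idx: list[int], K: int, kmeans_seed: int
) -> tuple[np.ndarray, np.ndarray, CSPModel]:
    """Fit CSPs on the training images and featurize every image."""
    groups = _class_order(np.array([d.group for d in data]))
    spaces = {
        g: np.concatenate(
            [data[i].primitives_um for i in train_idx if data[i].group == g]
        )
        for g in groups
    }
    model = fit_csp_model(spaces, K=K, seed=kmeans_seed)
    X = np.empty((len(data), model.M + 3))
    for i, d in enumerate(data):
        labels = assign_csp_labels(d.primitives_um, model)
        h = csp_histogram(labels, model.M)
        X[i] = augment_features(h, d.indices, model.M)
    y = np.array([d.group for d in data])
    return X, y, model


def _spatial_counts(tied: list[int], M: int, counts: dict[str, int]) -> None:
    for name_i, name in enumerate(SPATIAL_FEATURE_NAMES):
        if M + name_i in tied:
            counts[name] += 1


def train_test_evaluate(
    data: list[ImageData],
    K: int,
    split_seed: int,
    kmeans_seed: int,
    selection: str = "train",
) -> tuple[float, int, list[int], CSPModel]:
    """One random-split run: returns (test accuracy, best feature,
    tied-best features, fitted CSP model).

    ``selection`` decides the best-feature criterion: ``"train"``
    (default) scores candidates on the training images, ``"test"``
    on the held-out images (optimistically biased, but it is how the
    per-feature score of a train-and-test sweep is usually reported).
    """
    rng = np.random.default_rng(split_seed)
    train_idx, test_idx = split_train_test(data, rng)
    X, y, model = _build_features(data, train_idx, K, kmeans_seed)
    if selection == "train":
        j, clf, tied = select_best_feature(X[train_idx], y[train_idx])
    elif selection == "test":
        j, clf, tied = select_best_feature(
            X[train_idx], y[train_idx], X[test_idx], y[test_idx]
        )
    else:
        raise ValueError(f"selection must be 'train' or 'test', got {selection!r}")
    acc = clf.accuracy(X[test_idx][:, j], y[test_idx])
    return acc, j, tied, model


def repeated_evaluation(
    data: list[ImageData], K: int, n: int = 30, seed: int = 0,
    selection: str = "train",
) -> ExperimentResult:
    """n independent train/test runs with fresh split and k-means seeds."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    split_seeds = rng.integers(2**31, size=n)
    kmeans_seeds = rng.integers(2**31, size=n)
    accs = np.empty(n)
    counts = {name: 0 for name in SPATIAL_FEATURE_NAMES}
    best: list[int] = []
    M = None
    for r in range(n):
        acc, j, tied, model = train_test_evaluate(
            data, K, int(split_seeds[r]), int(kmeans_seeds[r]), selection=selection
        )
        accs[r] = acc
        best.append(j)
        M = model.M
        _spatial_counts(tied, M, counts)
    return ExperimentResult(
        protocol="train_test",
        n_runs=n,
        accuracies=accs,
        mean_accuracy=float(accs.mean()),
        sd_accuracy=float(accs.std(ddof=1)) if n > 1 else 0.0,
        index_counts=counts,
        feature_space_size=(M or 0) + 3,
        best_features=best,
    )


def loocv_evaluate(data: list[ImageData], K: int, seed: int = 0) -> ExperimentResult:
    """Leave-one-out CV with per-fold CSP refitting and feature selection."""
    S = len(data)
    if S < 2:
        raise ValueError("LOOCV requires at least 2 images")
    rng = np.random.default_rng(seed)
    kmeans_seeds = rng.integers(2**31, size=S)
    groups = _class_order(np.array([d.group for d in data]))
    correct = np.empty(S, dtype=bool)
    counts = {name: 0 for name in SPATIAL_FEATURE_NAMES}
    best: list[int] = []
    M = None
    for i in range(S):
        train_idx = [k for k in range(S) if k != i]
        fold_groups = {data[k].group for k in train_idx}
        if fold_groups != set(groups):
            raise ValueError(
                f"fold {i} loses class {set(groups) - fold_groups}; "
                "every class needs >= 2 images"
            )
        X, y, model = _build_features(data, train_idx, K, int(kmeans_seeds[i]))
        j, clf, tied = select_best_feature(X[train_idx], y[train_idx])
        correct[i] = clf.predict(X[i, j])[0] == data[i].group
        best.append(j)
        M = model.M
        _spatial_counts(tied, M, counts)
    acc = float(correct.mean())
    return ExperimentResult(
        protocol="loocv",
        n_runs=S,
        accuracies=correct.astype(float),
        mean_accuracy=acc,
        sd_accuracy=0.0,
        index_counts=counts,
        feature_space_size=(M or 0) + 3,
        S=S,
        best_features=best,
    )


def feature_analysis(
    data: list[ImageData], K: int, seed: int = 0
) -> ExperimentResult:
    """One split; record every feature reaching the maximal test score.

    When the best features are CSP histogram coordinates, the returned
    centre vectors describe the local shape patterns (chord length per
    angle) that discriminate between the groups.
    """
    rng = np.random.default_rng(seed)
    split_seed, kmeans_seed = (int(s) for s in rng.integers(2**31, size=2))
    split_rng = np.random.default_rng(split_seed)
    train_idx, test_idx = split_train_test(data, split_rng)
    X, y, model = _build_features(data, train_idx, K, kmeans_seed)
    j, clf, tied = select_best_feature(
        X[train_idx], y[train_idx], X[test_idx], y[test_idx]
    )
    best_score = clf.accuracy(X[test_idx][:, j], y[test_idx])
    names = feature_names(model)
    perfect = [(int(k), names[k]) for k in tied]
    centres = {
        int(k): model.centres[k].tolist() for k in tied if k < model.M
    }
    counts = {name: 0 for name in SPATIAL_FEATURE_NAMES}
    _spatial_counts(tied, model.M, counts)
    return ExperimentResult(
        protocol="feature_analysis",
        n_runs=1,
        accuracies=np.array([best_score]),
        mean_accuracy=best_score,
        sd_accuracy=0.0,
        index_counts=counts,
        feature_space_size=model.M + 3,
        best_features=[j],
        perfect_features=perfect,
        perfect_centres=centres,
        best_score=best_score,
    )
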