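"""Material-prediction experiment: repeated 70/30 holdout evaluation.

Three classifiers — linear SVM (unit regularization, no tuning), Gaussian
Naive Bayes, and 2-cluster K-means used as a classifier (clusters labeled by
training-set majority, test points assigned to the nearest centroid) — are
evaluated over repeated random swallow-level 70/30 splits, with and without
PCA to 8 components.  Standardization and PCA are fit on the training split
only.  Five performance measures are averaged across iterations: overall
accuracy, sensitivity to each material, and the predictive value of each
material's predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.naive_bayes import GaussianNB
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from hrca.screen import KEY_COLUMNS

CLASSIFIER_NAMES = ("svm_linear", "naive_bayes", "kmeans2")
METRIC_NAMES = (
    "overall_accuracy",
    "sensitivity_barium",
    "sensitivity_water",
    "predictive_value_barium",
    "predictive_value_water",
)


@dataclass
class EvalProtocol:
    n_iterations: int = 2000
    train_fraction: float = 0.70
    pca_components: Optional[int] = 8
    classifiers: Tuple[str, ...] = CLASSIFIER_NAMES
    seed: int = 0
    evaluate_raw: bool = True  # also run without dimensionality reduction

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        unknown = set(self.classifiers) - set(CLASSIFIER_NAMES)
        if unknown:
            raise ValueError(f"unknown classifiers: {sorted(unknown)}")


@dataclass
class ConfusionCounts:
    correct_barium: int
    total_barium_true: int
    correct_water: int
    total_water_true: int
    predicted_barium: int
    predicted_water: int

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if v < 0:
                raise ValueError(f"negative count {name}={v}")
        if self.correct_barium > min(self.total_barium_true, self.predicted_barium):
            raise ValueError("correct_barium exceeds its marginals")
        if self.correct_water > min(self.total_water_true, self.predicted_water):
            raise ValueError("correct_water exceeds its marginals")


def compute_performance(counts: ConfusionCounts) -> Dict[str, float]:
    """The five performance measures from one test split's confusion counts.

    Undefined ratios (an empty true class or an empty predicted class) are
    NaN and are excluded from that iteration's average downstream.
    """
    n = counts.total_barium_true + counts.total_water_true
    if n == 0:
        raise ValueError("empty test split")

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else np.nan

    return {
        "overall_accuracy": (counts.correct_barium + counts.correct_water) / n,
        "sensitivity_barium": ratio(counts.correct_barium, counts.total_barium_true),
        "sensitivity_water": ratio(counts.correct_water, counts.total_water_true),
        "predictive_value_barium": ratio(counts.correct_barium, counts.predicted_barium),
        "predictive_value_water": ratio(counts.correct_water, counts.predicted_water),
    }


def counts_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    barium = y_true == "barium"
    water = y_true == "water"
    pred_b = y_pred == "barium"
    pred_w = y_pred == "water"
    return ConfusionCounts(
        correct_barium=int(np.sum(barium & pred_b)),
        total_barium_true=int(barium.sum()),
        correct_water=int(np.sum(water & pred_w)),
        total_water_true=int(water.sum()),
        predicted_barium=int(pred_b.sum()),
        predicted_water=int(pred_w.sum()),
    )


def pca_reduce(
    train_X: np.ndarray, test_X: np.ndarray, k: int
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Project both splits onto ``k`` principal components fit on training data.

    Inputs are expected already standardized on training statistics.  Returns
    the training-fit explained-variance fraction alongside the projections.
    """
    if k > min(train_X.shape):
        raise ValueError(f"k={k} exceeds data rank bound {min(train_X.shape)}")
    pca = PCA(n_components=k, svd_solver="full")
    train_scores = pca.fit_transform(train_X)
    return train_scores, pca.transform(test_X), float(pca.explained_variance_ratio_.sum())


def kmeans_classify(
    train_X: np.ndarray,
    train_labels: np.ndarray,
    test_X: np.ndarray,
    seed: int,
    n_init: int = 5,
) -> np.ndarray:
    """2-means on training features, clusters labeled by training majority.

    Test points take the label of the nearest centroid.  A cluster with a
    tied majority takes the lexicographically smallest label; if both
    clusters map to the same label the degenerate constant prediction is
    returned as-is.
    """
    labels = np.unique(train_labels)
    if len(labels) < 2:
        raise ValueError("both labels required in training data")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        km = KMeans(n_clusters=2, n_init=n_init, random_state=seed)
        train_assign = km.fit_predict(train_X)
    cluster_label = {}
    for cl in (0, 1):
        members = train_labels[train_assign == cl]
        if len(members) == 0:
            cluster_label[cl] = sorted(labels)[0]
            continue
        uniq, counts = np.unique(members, return_counts=True)
        winners = sorted(uniq[counts == counts.max()])
        cluster_label[cl] = winners[0]
    test_assign = km.predict(test_X)
    return np.asarray([cluster_label[cl] for cl in test_assign])


def _predict(
    name: str,
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    seed: int,
) -> np.ndarray:
    if name == "svm_linear":
        clf = SVC(kernel="linear", C=1.0)
        clf.fit(train_X, train_y)
        return clf.predict(test_X)
    if name == "naive_bayes":
        clf = GaussianNB()
        clf.fit(train_X, train_y)
        return clf.predict(test_X)
    if name == "kmeans2":
        return kmeans_classify(train_X, train_y, test_X, seed)
    raise ValueError(f"unknown classifier {name!r}")


@dataclass
class PerformanceReport:
    """Iteration-averaged metrics per classifier for raw and PCA variants."""

    metrics: Dict[str, Dict[str, Dict[str, float]]]  # variant -> classifier -> metric -> mean
    metric_sds: Dict[str, Dict[str, Dict[str, float]]]
    pca_explained_variance: Optional[float]
    n_iterations: int
    n_redrawn_splits: int = 0
    n_undefined_metrics: int = 0

    def to_dict(self) -> dict:
        return {
            "n_iterations": self.n_iterations,
            "pca_explained_variance": self.pca_explained_variance,
            "n_redrawn_splits": self.n_redrawn_splits,
            "n_undefined_metrics": self.n_undefined_metrics,
            "metrics": self.metrics,
            "metric_sds": self.metric_sds,
        }


def holdout_evaluate(
    table: pd.DataFrame,
    protocol: Optional[EvalProtocol] = None,
    feature_columns: Optional[List[str]] = None,
) -> PerformanceReport:
    """Run the repeated-holdout material-prediction experiment.

    Per iteration: a uniform random swallow-level 70/30 split (redrawn, with a
    logged count, if a material is missing from the training split),
    z-scoring on training statistics, an optional PCA variant, then every
    classifier fit and scored on the test split.  Metrics are averaged over
    iterations; undefined metrics (empty predicted class) are excluded from
    their average.  Fully seeded and deterministic.
    """
    protocol = protocol or EvalProtocol()
    if feature_columns is None:
        feature_columns = [c for c in table.columns if c not in KEY_COLUMNS]
    work = table.dropna(subset=feature_columns)
    X_all = work[feature_columns].to_numpy(dtype=float)
    y_all = work["material"].to_numpy()
    n = len(work)
    for mat in ("barium", "water"):
        if np.sum(y_all == mat) < 10:
            raise ValueError(f"need >= 10 rows per material, {mat} has {np.sum(y_all == mat)}")
    n_train = int(round(protocol.train_fraction * n))

    variants = ["pca"] if protocol.pca_components else []
    if protocol.evaluate_raw or not variants:
        variants = ["raw"] + variants

    rng = np.random.default_rng(np.random.SeedSequence([protocol.seed, 2]))
    acc: Dict[str, Dict[str, Dict[str, List[float]]]] = {
        v: {c: {m: [] for m in METRIC_NAMES} for c in protocol.classifiers} for v in variants
    }
    evr_values: List[float] = []
    n_redrawn = 0
    n_undefined = 0

    for _ in range(protocol.n_iterations):
        while True:
            perm = rng.permutation(n)
            train_idx, test_idx = perm[:n_train], perm[n_train:]
            if len(np.unique(y_all[train_idx])) == 2:
                break
            n_redrawn += 1
        km_seed = int(rng.integers(0, 2**31 - 1))
        scaler = StandardScaler()
        with np.errstate(invalid="ignore", divide="ignore"):
            train_X = scaler.fit_transform(X_all[train_idx])
            test_X = scaler.transform(X_all[test_idx])
        train_X = np.nan_to_num(train_X)
        test_X = np.nan_to_num(test_X)
        train_y, test_y = y_all[train_idx], y_all[test_idx]

        split_variants = {}
        if "raw" in acc:
            split_variants["raw"] = (train_X, test_X)
        if "pca" in acc:
            tr, te, evr = pca_reduce(train_X, test_X, protocol.pca_components)
            split_variants["pca"] = (tr, te)
            evr_values.append(evr)

        for variant, (tr, te) in split_variants.items():
            for name in protocol.classifiers:
                pred = _predict(name, tr, train_y, te, km_seed)
                metrics = compute_performance(counts_from_predictions(test_y, pred))
                for m, v in metrics.items():
                    if np.isnan(v):
                        n_undefined += 1
                    else:
                        acc[variant][name][m].append(v)

    means = {
        v: {c: {m: float(np.mean(vals)) if vals else np.nan for m, vals in d.items()}
            for c, d in byc.items()}
        for v, byc in acc.items()
    }
    sds = {
        v: {c: {m: float(np.std(vals)) if vals else np.nan for m, vals in d.items()}
            for c, d in byc.items()}
        for v, byc in acc.items()
    }
    return PerformanceReport(
        metrics=means,
        metric_sds=sds,
        pca_explained_variance=float(np.mean(evr_values)) if evr_values else None,
        n_iterations=protocol.n_iterations,
        n_redrawn_splits=n_redrawn,
        n_undefined_metrics=n_undefined,
    )
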