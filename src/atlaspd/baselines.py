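"""Classical comparators: SVM, random forest, k-NN, and a BP neural network.

Each comparator runs with fixed, declared hyperparameters:
SVM (C=0.8, gamma='scale', RBF kernel, pairwise-coupled probabilities),
RF (80 trees, depth 8, min_samples_split 8), k-NN (k=7, distance weights,
kd-tree), BP-NN (hidden layers (80, 40), alpha 0.02, 180 iterations).

Classical models cannot consume raw channels-by-time series; the default
"summary" featurization reduces each channel to five statistics (task-block
mean, rest mean, task-rest difference, sd, slope), 110 features for the
22-channel montage.  A "flatten" mode concatenating the decimated series is
also available.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .design import BlockDesign
from .preprocess import DatasetTensor

__all__ = ["BASELINE_NAMES", "featurize", "make_baseline", "fit_baseline",
           "BaselineClassifier", "cross_validate"]

BASELINE_NAMES = ("svm", "rf", "knn", "bpnn")

_STAT_NAMES = ("task_mean", "rest_mean", "task_minus_rest", "sd", "slope")


def featurize(dataset, mode: str = "summary", design: BlockDesign | None = None,
              sampling_hz: float | None = None, channel_ids=None
              ) -> tuple[np.ndarray, list[str]]:
    """Reduce an (N, C, T) tensor to a per-subject feature matrix.

    Returns (features, feature_names); names are ``<channel>:<statistic>``.
    """
    if isinstance(dataset, DatasetTensor):
        X = dataset.data
        design = design or dataset.design
        sampling_hz = sampling_hz or dataset.sampling_hz
        channel_ids = channel_ids or dataset.channel_ids
    else:
        X = np.asarray(dataset)
    n, c, t = X.shape
    if channel_ids is None:
        channel_ids = [f"CH{i + 1:02d}" for i in range(c)]

    if mode == "flatten":
        names = [f"{ch}:t{j}" for ch in channel_ids for j in range(t)]
        return X.reshape(n, c * t).astype(float), names
    if mode != "summary":
        raise ValueError(f"unknown featurization mode {mode!r}")
    if design is None or sampling_hz is None:
        raise ValueError("summary mode needs the block design and sampling rate")

    task = design.task_mask(sampling_hz)[:t]
    rest = design.rest_mask(sampling_hz)[:t]
    if not task.any() or not rest.any():
        raise ValueError("design yields empty task or rest mask at this length")
    tt = np.arange(t) / sampling_hz
    tt = tt - tt.mean()
    denom = float((tt ** 2).sum())

    task_mean = X[:, :, task].mean(axis=2)
    rest_mean = X[:, :, rest].mean(axis=2)
    sd = X.std(axis=2)
    slope = (X * tt).sum(axis=2) / denom
    feats = np.stack([task_mean, rest_mean, task_mean - rest_mean, sd, slope],
                     axis=2).reshape(n, c * len(_STAT_NAMES))
    names = [f"{ch}:{s}" for ch in channel_ids for s in _STAT_NAMES]
    return feats.astype(float), names


def make_baseline(name: str, seed: int = 42):
    """Instantiate one of the four comparators with its fixed hyperparameters."""
    if name == "svm":
        return SVC(C=0.8, gamma="scale", kernel="rbf", probability=True,
                   random_state=seed)
    if name == "rf":
        return RandomForestClassifier(n_estimators=80, max_depth=8,
                                      min_samples_split=8, random_state=seed)
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=7, weights="distance",
                                    algorithm="kd_tree")
    if name == "bpnn":
        return MLPClassifier(hidden_layer_sizes=(80, 40), alpha=0.02,
                             max_iter=180, random_state=seed)
    raise ValueError(f"unknown baseline {name!r}")


def fit_baseline(name: str, features: np.ndarray, labels: np.ndarray,
                 seed: int = 42):
    """Fit a comparator on a precomputed feature matrix (features are
    standardized inside the returned pipeline; no leakage across fits)."""
    features = np.asarray(features, dtype=float)
    if not np.isfinite(features).all():
        raise ValueError("features must be finite")
    pipe = Pipeline([("scale", StandardScaler()),
                     ("model", make_baseline(name, seed))])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MLP convergence at fixed max_iter
        pipe.fit(features, labels)
    return pipe


class BaselineClassifier(BaseEstimator, ClassifierMixin):
    """Sklearn-style wrapper: featurization recipe + scaler + comparator.

    Accepts the same (N, C, T) tensors as the deep models so evaluation,
    robustness, and importance analyses treat all classifiers uniformly.
    """

    def __init__(self, name: str = "rf", mode: str = "summary",
                 design: BlockDesign | None = None,
                 sampling_hz: float | None = None, seed: int = 42):
        self.name = name
        self.mode = mode
        self.design = design
        self.sampling_hz = sampling_hz
        self.seed = seed

    def _features(self, X):
        if isinstance(X, DatasetTensor):
            return featurize(X, self.mode)[0]
        return featurize(X, self.mode, self.design, self.sampling_hz)[0]

    def fit(self, X, y=None):
        if isinstance(X, DatasetTensor):
            y = np.asarray(X.labels)
        f = self._features(X)
        self.pipeline_ = fit_baseline(self.name, f, np.asarray(y), self.seed)
        self.classes_ = self.pipeline_.classes_
        return self

    def predict_proba(self, X):
        return self.pipeline_.predict_proba(self._features(X))

    def predict(self, X):
        return self.pipeline_.predict(self._features(X))


def cross_validate(name: str, features: np.ndarray, labels: np.ndarray,
                   folds: int = 5, seed: int = 42) -> pd.DataFrame:
    """Stratified k-fold accuracy/macro-F1 for one comparator.

    Folds are disjoint and exhaustive with near-equal class mix; the caller
    refits on the full set before test evaluation (see :func:`fit_baseline`).
    """
    from sklearn.metrics import f1_score
    from sklearn.model_selection import StratifiedKFold

    labels = np.asarray(labels)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    counts = pd.Series(labels).value_counts()
    if (counts < folds).any():
        raise ValueError("every class needs at least `folds` members")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    rows = []
    for k, (tr, te) in enumerate(skf.split(features, labels)):
        pipe = fit_baseline(name, features[tr], labels[tr], seed)
        pred = pipe.predict(features[te])
        rows.append({
            "fold": k, "n_test": len(te),
            "accuracy": float((pred == labels[te]).mean()),
            "macro_f1": float(f1_score(labels[te], pred, average="macro")),
        })
    return pd.DataFrame(rows)
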