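"""Metrics, paired statistical tests, noise robustness, and power utilities.

Covers the full evaluation protocol: confusion-matrix metrics with
percentile-bootstrap confidence intervals, one-vs-rest ROC AUC per class,
McNemar's paired test with continuity correction (exact binomial branch for
small discordant counts), the Gaussian noise-injection robustness curve and
its normalized area (AUC_robustness), and one-way-ANOVA power / sample-size
arithmetic on the noncentral F distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EvalReport", "RobustnessCurve", "PairedComparison",
    "evaluate_classifier", "mcnemar_test", "noise_robustness",
    "cohens_d", "cohens_f_from_eta2", "anova_power", "anova_sample_size",
]

DEFAULT_SIGMAS: tuple[float, ...] = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)


# ---------------------------------------------------------------------------
# report containers

@dataclass
class EvalReport:
    classes: tuple[str, ...]
    confusion: np.ndarray
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    sensitivity: dict[str, float]
    specificity: dict[str, float]
    auc: dict[str, float | None]
    macro_auc: float | None
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "macro_auc": self.macro_auc,
            "ci": {k: list(v) for k, v in self.ci.items()},
        }


@dataclass
class RobustnessCurve:
    sigmas: np.ndarray
    accuracy: np.ndarray
    macro_auc: np.ndarray
    auc_robustness: float
    reps: int

    def __post_init__(self) -> None:
        s = np.asarray(self.sigmas, dtype=float)
        if s[0] != 0 or np.any(np.diff(s) <= 0):
            raise ValueError("sigma grid must start at 0 and increase strictly")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sigma": self.sigmas, "accuracy": self.accuracy,
                             "macro_auc": self.macro_auc})


@dataclass
class PairedComparison:
    statistic: float
    p_value: float
    b: int
    c: int
    exact: bool
    accuracy_difference: float | None = None
    diff_ci: tuple[float, float] | None = None
    superiority_p: float | None = None


# ---------------------------------------------------------------------------
# confusion-matrix metrics

def _metrics_from_counts(cm: np.ndarray) -> dict:
    n = cm.sum()
    k = cm.shape[0]
    tp = np.diag(cm).astype(float)
    row = cm.sum(axis=1).astype(float)     # actual counts
    col = cm.sum(axis=0).astype(float)     # predicted counts
    with np.errstate(invalid="ignore", divide="ignore"):
        sens = np.where(row > 0, tp / row, np.nan)
        prec = np.where(col > 0, tp / col, np.nan)
        spec = np.where(n - row > 0, (n - row - col + tp) / (n - row), np.nan)
        f1 = np.where(prec + sens > 0, 2 * prec * sens / (prec + sens), 0.0)
    return {
        "accuracy": float(tp.sum() / n) if n else float("nan"),
        "precision": prec, "recall": sens, "specificity": spec, "f1": f1, "k": k,
    }


def evaluate_classifier(model, X_test, y_test=None, bootstrap_n: int = 1000,
                        seed: int = 0, classes=None) -> EvalReport:
    """Full test-set evaluation with percentile-bootstrap 95% CIs.

    ``model`` must expose ``predict_proba`` (rows summing to 1) and
    ``classes_``; ``X_test`` may be a DatasetTensor carrying its labels.
    A class absent from the test set gets a missing (None) AUC.
    """
    from sklearn.metrics import confusion_matrix, roc_auc_score

    from .preprocess import DatasetTensor

    if isinstance(X_test, DatasetTensor) and y_test is None:
        y_test = np.asarray(X_test.labels)
    y_test = np.asarray(y_test)
    proba = np.asarray(model.predict_proba(X_test))
    classes = tuple(classes if classes is not None else model.classes_)
    pred = np.asarray(classes)[proba.argmax(axis=1)]

    cm = confusion_matrix(y_test, pred, labels=list(classes))
    m = _metrics_from_counts(cm)

    auc: dict[str, float | None] = {}
    for j, cls in enumerate(classes):
        pos = (y_test == cls).astype(int)
        if pos.min() == pos.max():
            auc[cls] = None
        else:
            auc[cls] = float(roc_auc_score(pos, proba[:, j]))
    defined = [v for v in auc.values() if v is not None]
    macro_auc = float(np.mean(defined)) if defined else None

    rng = np.random.default_rng(seed)
    n = len(y_test)
    stats_boot = {"accuracy": [], "macro_f1": [], "macro_auc": []}
    for _ in range(bootstrap_n):
        idx = rng.integers(0, n, size=n)
        cm_b = confusion_matrix(y_test[idx], pred[idx], labels=list(classes))
        mb = _metrics_from_counts(cm_b)
        stats_boot["accuracy"].append(mb["accuracy"])
        stats_boot["macro_f1"].append(float(np.nanmean(mb["f1"])))
        aucs = []
        for j, cls in enumerate(classes):
            pos = (y_test[idx] == cls).astype(int)
            if pos.min() != pos.max():
                aucs.append(roc_auc_score(pos, proba[idx, j]))
        stats_boot["macro_auc"].append(float(np.mean(aucs)) if aucs else np.nan)
    ci = {k: (float(np.nanpercentile(v, 2.5)), float(np.nanpercentile(v, 97.5)))
          for k, v in stats_boot.items() if len(v)}

    return EvalReport(
        classes=classes,
        confusion=cm,
        accuracy=m["accuracy"],
        macro_precision=float(np.nanmean(m["precision"])),
        macro_recall=float(np.nanmean(m["recall"])),
        macro_f1=float(np.nanmean(m["f1"])),
        sensitivity={c: float(s) for c, s in zip(classes, m["recall"])},
        specificity={c: float(s) for c, s in zip(classes, m["specificity"])},
        auc=auc,
        macro_auc=macro_auc,
        ci=ci,
    )


# ---------------------------------------------------------------------------
# paired tests

def mcnemar_test(preds_a, preds_b, labels, correction: bool = True,
                 exact_threshold: int = 25) -> PairedComparison:
    """McNemar's test on the paired error patterns of two classifiers.

    ``b`` counts items A got right and B wrong; ``c`` the reverse.  The
    continuity-corrected statistic is (|b-c|-1)^2/(b+c); the p-value uses
    the exact binomial distribution when b+c < ``exact_threshold``.
    """
    a = np.asarray(preds_a) == np.asarray(labels)
    bb = np.asarray(preds_b) == np.asarray(labels)
    if a.shape != bb.shape:
        raise ValueError("prediction vectors must be aligned")
    b = int(np.sum(a & ~bb))
    c = int(np.sum(~a & bb))
    n_disc = b + c
    if n_disc == 0:
        return PairedComparison(0.0, 1.0, b, c, exact=False)
    if correction:
        stat = (abs(b - c) - 1) ** 2 / n_disc if abs(b - c) > 1 else 0.0
    else:
        stat = (b - c) ** 2 / n_disc
    if n_disc < exact_threshold:
        p = float(min(1.0, 2.0 * stats.binom.cdf(min(b, c), n_disc, 0.5)))
        exact = True
    else:
        p = float(stats.chi2.sf(stat, df=1))
        exact = False
    return PairedComparison(float(stat), p, b, c, exact)


def bootstrap_accuracy_difference(preds_a, preds_b, labels, n_boot: int = 1000,
                                  seed: int = 0) -> PairedComparison:
    """Bootstrap CI and superiority p-value for accuracy(A) - accuracy(B)."""
    rng = np.random.default_rng(seed)
    a = np.asarray(preds_a) == np.asarray(labels)
    bb = np.asarray(preds_b) == np.asarray(labels)
    n = len(a)
    diffs = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        diffs[i] = a[idx].mean() - bb[idx].mean()
    base = mcnemar_test(preds_a, preds_b, labels)
    base.accuracy_difference = float(a.mean() - bb.mean())
    base.diff_ci = (float(np.percentile(diffs, 2.5)),
                    float(np.percentile(diffs, 97.5)))
    base.superiority_p = float(np.mean(diffs <= 0))
    return base


# ---------------------------------------------------------------------------
# noise robustness

def auc_robustness_from_curve(sigmas, accuracies) -> float:
    """Trapezoidal area of accuracy over sigma, normalized by the sigma
    range, so a constant accuracy of 1 scores exactly 1."""
    s = np.asarray(sigmas, dtype=float)
    a = np.asarray(accuracies, dtype=float)
    if len(s) < 2:
        return float(a[0])
    return float(np.trapezoid(a, s) / (s[-1] - s[0]))


def noise_robustness(model, X_test, y_test=None,
                     sigmas=DEFAULT_SIGMAS, reps: int = 20,
                     seed: int = 0) -> RobustnessCurve:
    """Accuracy (and macro AUC) under additive Gaussian input noise.

    ``X_noisy = X + N(0, sigma^2)`` in the units of the already-normalized
    input; sigma = 0 reproduces the clean accuracy exactly (no noise draw).
    Each positive sigma is averaged over ``reps`` seeded draws.
    """
    from sklearn.metrics import roc_auc_score

    from .preprocess import DatasetTensor

    if isinstance(X_test, DatasetTensor):
        y_test = np.asarray(X_test.labels) if y_test is None else np.asarray(y_test)
        X_test = X_test.data
    y_test = np.asarray(y_test)
    X_test = np.asarray(X_test)
    s = np.asarray(sigmas, dtype=float)
    if np.any(s < 0):
        raise ValueError("noise levels must be non-negative")
    classes = list(model.classes_)
    rng = np.random.default_rng(seed)

    def score(X):
        proba = np.asarray(model.predict_proba(X))
        pred = np.asarray(classes)[proba.argmax(axis=1)]
        acc = float((pred == y_test).mean())
        aucs = []
        for j, cls in enumerate(classes):
            pos = (y_test == cls).astype(int)
            if pos.min() != pos.max():
                aucs.append(roc_auc_score(pos, proba[:, j]))
        return acc, (float(np.mean(aucs)) if aucs else float("nan"))

    accs, aucs = [], []
    for sigma in s:
        if sigma == 0:
            a, u = score(X_test)
            accs.append(a)
            aucs.append(u)
            continue
        aa, uu = [], []
        for _ in range(reps):
            noisy = X_test + rng.normal(0.0, sigma, size=X_test.shape)
            a, u = score(noisy)
            aa.append(a)
            uu.append(u)
        accs.append(float(np.mean(aa)))
        aucs.append(float(np.mean(uu)))
    return RobustnessCurve(s, np.asarray(accs), np.asarray(aucs),
                           auc_robustness_from_curve(s, accs), reps)


# ---------------------------------------------------------------------------
# effect sizes and power

def cohens_d(mean1: float, sd1: float, n1: int,
             mean2: float, sd2: float, n2: int) -> float:
    """Standardized mean difference with the pooled standard deviation."""
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    pooled = np.sqrt(((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / (n1 + n2 - 2))
    if pooled == 0:
        raise ValueError("pooled standard deviation is zero")
    return float((mean2 - mean1) / pooled)


def cohens_f_from_eta2(eta2: float) -> float:
    """Cohen's f = sqrt(eta^2 / (1 - eta^2))."""
    if not 0 <= eta2 < 1:
        raise ValueError("eta squared must lie in [0, 1)")
    return float(np.sqrt(eta2 / (1.0 - eta2)))


def anova_power(f: float, k: int, n_total: int, alpha: float = 0.05) -> float:
    """Power of a one-way ANOVA via the noncentral F distribution.

    df = (k-1, N-k), noncentrality lambda = f^2 * N.
    """
    if f <= 0:
        raise ValueError("effect size f must be positive")
    if k < 2 or n_total <= k:
        raise ValueError("need k >= 2 groups and N > k")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    df1, df2 = k - 1, n_total - k
    crit = stats.f.isf(alpha, df1, df2)
    return float(stats.ncf.sf(crit, df1, df2, f * f * n_total))


def anova_sample_size(f: float, k: int = 3, alpha: float = 0.05,
                      power: float = 0.80, n_max: int = 1_000_000) -> int:
    """Smallest total N (equal allocation) whose ANOVA power reaches target."""
    if not 0 < power < 1:
        raise ValueError("power must lie in (0, 1)")
    n = k + 1
    while n <= n_max:
        if anova_power(f, k, n, alpha) >= power:
            return n
        n += 1
    raise ValueError("target power unattainable within n_max")
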