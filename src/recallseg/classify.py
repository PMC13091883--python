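"""Recall classification harness: LOOCV, shuffle null, paired test, calibration.

Features are the flattened (W*M, r) edge vectors of one variant — the raw FC
tensor, its low-rank component, or its sparse (idiosyncratic) component — with
scene-level high/low recall labels.  Evaluation is leave-one-out
cross-validation, either per sample or grouped per subject (so no subject's
scenes sit in both train and test), with a seeded bootstrap CI over fold
outcomes and a within-story label-shuffling null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import expit
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import balanced_accuracy_score, roc_auc_score
from sklearn.svm import LinearSVC

__all__ = [
    "ClassifierSpec",
    "FoldRecord",
    "ClassificationReport",
    "run_loocv",
    "shuffle_null",
    "paired_accuracy_test",
    "calibration_curve",
]


@dataclass(frozen=True)
class ClassifierSpec:
    """One of the three classifier families with its regularization.

    family : 'logistic' | 'random_forest' | 'svm'
    l2_c : inverse l2 strength for logistic / linear SVM (sklearn's ``C``).
    n_trees, max_depth : random forest size.
    seed : RNG seed for the forest.
    """

    family: str = "logistic"
    l2_c: float = 1.0
    n_trees: int = 100
    max_depth: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("logistic", "random_forest", "svm"):
            raise ValueError(f"unknown classifier family {self.family!r}")

    def build(self):
        if self.family == "logistic":
            return LogisticRegression(C=self.l2_c, max_iter=2000)
        if self.family == "svm":
            return LinearSVC(C=self.l2_c, max_iter=5000)
        return RandomForestClassifier(
            n_estimators=self.n_trees,
            max_depth=self.max_depth,
            random_state=self.seed,
        )


def _predict_proba(clf, x: np.ndarray) -> np.ndarray:
    """P(class 1).  Margin classifiers use a logistic squashing of the margin
    (monotone, so ranking metrics are exact; calibration is approximate)."""
    if hasattr(clf, "predict_proba"):
        return clf.predict_proba(x)[:, list(clf.classes_).index(1)]
    return expit(clf.decision_function(x))


@dataclass
class FoldRecord:
    held_out: np.ndarray  # sample indices
    y_true: np.ndarray
    y_pred: np.ndarray
    proba: np.ndarray
    skipped: bool = False


@dataclass
class ClassificationReport:
    variant: str
    classifier: ClassifierSpec
    accuracy: float
    balanced_accuracy: float
    auc: float
    ci95: tuple[float, float]
    folds: list[FoldRecord] = field(default_factory=list)
    shuffle_accuracy: float | None = None
    calibration: list[dict] | None = None
    cv_unit: str = "sample"

    def pooled(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        y = np.concatenate([f.y_true for f in self.folds if not f.skipped])
        p = np.concatenate([f.y_pred for f in self.folds if not f.skipped])
        pr = np.concatenate([f.proba for f in self.folds if not f.skipped])
        return y, p, pr


def run_loocv(
    features: np.ndarray,
    labels: np.ndarray,
    spec: ClassifierSpec = ClassifierSpec(),
    unit: str = "sample",
    groups: np.ndarray | None = None,
    seed: int = 0,
    n_bootstrap: int = 1000,
    variant: str = "fc",
) -> ClassificationReport:
    """Leave-one-out cross-validation with bootstrap CI.

    ``unit='sample'`` holds out one row per fold; ``unit='subject'`` holds out
    all rows of one subject (``groups`` required), so no subject leaks across
    the split.  Accuracy is mean held-out correctness; balanced accuracy and
    AUC are computed on the pooled held-out predictions; the 95% CI is a
    seeded percentile bootstrap (``n_bootstrap`` resamples) over per-fold
    outcomes.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if x.ndim != 2 or x.shape[0] != y.shape[0]:
        raise ValueError("features must be (n, r) aligned with labels")
    if unit == "subject":
        if groups is None:
            raise ValueError("unit='subject' requires a subject index per sample")
        fold_ids = [np.nonzero(groups == g)[0] for g in np.unique(groups)]
    elif unit == "sample":
        fold_ids = [np.array([i]) for i in range(x.shape[0])]
    else:
        raise ValueError(f"unknown CV unit {unit!r}")

    folds: list[FoldRecord] = []
    warm = None
    for held in fold_ids:
        mask = np.ones(x.shape[0], dtype=bool)
        mask[held] = False
        y_tr = y[mask]
        if np.unique(y_tr).size < 2:
            warnings.warn(
                f"fold holding out {held[:3]}...: single-class training set, skipped",
                stacklevel=2,
            )
            folds.append(
                FoldRecord(held, y[held], np.empty(0, int), np.empty(0), skipped=True)
            )
            continue
        if spec.family == "logistic":
            # warm-start consecutive convex fits; the optimum is unique so
            # results are init-independent, only faster
            if warm is None:
                warm = LogisticRegression(C=spec.l2_c, max_iter=2000, warm_start=True)
            clf = warm
        else:
            clf = spec.build()
        clf.fit(x[mask], y_tr)
        folds.append(
            FoldRecord(held, y[held], clf.predict(x[held]), _predict_proba(clf, x[held]))
        )

    if all(f.skipped for f in folds):
        raise ValueError(
            "every fold had a single-class training set; labels are (nearly) "
            "constant"
        )
    y_true, y_pred, proba = (
        np.concatenate([f.y_true for f in folds if not f.skipped]),
        np.concatenate([f.y_pred for f in folds if not f.skipped]),
        np.concatenate([f.proba for f in folds if not f.skipped]),
    )
    correct = y_true == y_pred
    acc = float(np.mean(correct))
    bal = float(balanced_accuracy_score(y_true, y_pred))
    auc = float(roc_auc_score(y_true, proba)) if np.unique(y_true).size == 2 else float("nan")

    # per-fold mean correctness, bootstrapped
    fold_acc = np.array(
        [np.mean(f.y_true == f.y_pred) for f in folds if not f.skipped]
    )
    rng = np.random.default_rng(seed)
    boots = rng.choice(fold_acc, size=(n_bootstrap, fold_acc.size), replace=True).mean(axis=1)
    ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))

    return ClassificationReport(
        variant=variant,
        classifier=spec,
        accuracy=acc,
        balanced_accuracy=bal,
        auc=auc,
        ci95=ci,
        folds=folds,
        cv_unit=unit,
    )


def shuffle_null(
    features: np.ndarray,
    labels: np.ndarray,
    spec: ClassifierSpec = ClassifierSpec(),
    n_shuffles: int = 100,
    seed: int = 0,
    story_ids: np.ndarray | None = None,
    unit: str = "sample",
    groups: np.ndarray | None = None,
) -> dict:
    """Label-shuffling null distribution of LOOCV accuracy.

    Labels are permuted within story (preserving each story's class balance)
    and the full LOOCV is re-run per permutation.  Returns the null draws,
    their mean/sd, the observed accuracy and its percentile in the null.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if n_shuffles < 20:
        warnings.warn(
            f"n_shuffles={n_shuffles} gives at best {100 / (n_shuffles + 1):.0f}% "
            "percentile resolution",
            stacklevel=2,
        )
    y = np.asarray(labels, dtype=int)
    stories = np.zeros(y.size, dtype=int) if story_ids is None else np.asarray(story_ids)
    rng = np.random.default_rng(seed)

    observed = run_loocv(features, y, spec, unit=unit, groups=groups, seed=seed).accuracy
    null = np.empty(n_shuffles)
    for i in range(n_shuffles):
        y_perm = y.copy()
        for s in np.unique(stories):
            idx = np.nonzero(stories == s)[0]
            y_perm[idx] = y[rng.permutation(idx)]
        null[i] = run_loocv(features, y_perm, spec, unit=unit, groups=groups, seed=seed).accuracy

    out = {
        "null_accuracies": null,
        "null_mean": float(null.mean()),
        "null_sd": float(null.std(ddof=1)) if n_shuffles > 1 else float("nan"),
        "observed_accuracy": float(observed),
        "majority_baseline": float(max(np.mean(y), 1 - np.mean(y))),
    }
    if n_shuffles > 1:
        out["observed_percentile"] = float(100.0 * np.mean(null < observed))
    return out


def paired_accuracy_test(acc_a: np.ndarray, acc_b: np.ndarray) -> dict:
    """Paired t test on per-run accuracies of two variants.

    Returns the mean difference (b - a), t statistic and p value; a constant
    non-zero difference (zero variance) is reported as t = inf, p = 0, and an
    identically-zero difference as t = 0, p = 1.
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired accuracy vectors must be 1-D and equal length")
    if a.size < 3:
        raise ValueError("need at least 3 paired runs")
    d = b - a
    delta = float(d.mean())
    if np.allclose(d.std(ddof=1), 0.0):
        if delta == 0.0:
            return {"delta": 0.0, "t": 0.0, "p": 1.0}
        return {"delta": delta, "t": float(np.inf) * np.sign(delta), "p": 0.0}
    t, p = stats.ttest_rel(b, a)
    return {"delta": delta, "t": float(t), "p": float(p)}


def calibration_curve(proba: np.ndarray, labels: np.ndarray, n_bins: int = 10) -> list[dict]:
    """Equal-width reliability bins of predicted probability vs observed rate."""
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    p = np.asarray(proba, dtype=float)
    y = np.asarray(labels, dtype=int)
    if p.size != y.size:
        raise ValueError("probabilities and labels must align")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities outside [0, 1]")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(p, edges[1:-1]), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        m = which == b
        n = int(m.sum())
        rows.append(
            {
                "bin": b,
                "lo": float(edges[b]),
                "hi": float(edges[b + 1]),
                "count": n,
                "mean_predicted": float(p[m].mean()) if n else float("nan"),
                "observed_frequency": float(y[m].mean()) if n else float("nan"),
                "empty": n == 0,
            }
        )
    return rows
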