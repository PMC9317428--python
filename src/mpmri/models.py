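"""Balanced leave-one-out classifier comparison for pCR prediction.

The cohort is first balanced by keeping every responder and an equal-size
random subset of non-responders.  Ten classifier families are then trained
and evaluated with leave-one-out cross-validation (LOOCV) on three feature
configurations — imaging, clinical, and imaging + clinical — and summarised
by confusion matrices and accuracy / sensitivity / specificity / error
rate, with pCR as the positive class throughout.

Hyperparameters are fixed, seeded defaults (no tuning): the claims carried
by this module are ordering properties between configurations, not tuned
absolute accuracies.  Scale-sensitive learners (K-NN, MLP, LR, LDA, QDA)
standardise features inside each training fold only; tree ensembles run on
raw features.  QDA uses shrinkage regularisation, since with ~24 samples
and tens of features the per-class covariances are otherwise singular.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "CLASSIFIERS",
    "ConfusionMatrix",
    "ModelMetrics",
    "balance",
    "make_classifier",
    "loocv",
    "confusion_metrics",
    "compare_configurations",
]

CLASSIFIERS = ("knn", "dt", "rf", "adaboost", "gboost", "gnb", "lda", "qda", "mlp", "lr")
_SCALED = {"knn", "mlp", "lr", "lda", "qda"}


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with pCR as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class ModelMetrics:
    """Percentages; ratios with a zero denominator are None (not 0)."""

    accuracy: float
    sensitivity: float | None
    specificity: float | None
    error_rate: float


class ShrinkageQDA(BaseEstimator, ClassifierMixin):
    """Quadratic discriminant analysis with shrunk class covariances.

    Per class c the covariance is Sigma_c = (1 - alpha) S_c +
    alpha (tr S_c / p) I, which stays positive definite when the class has
    fewer samples than features — the regime of a ~12-per-class cohort with
    tens of features, where an unshrunk QDA is ill-posed.  Prediction is
    the usual Gaussian quadratic discriminant with empirical class priors.
    """

    def __init__(self, alpha: float = 0.5):
        self.alpha = alpha

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        p = X.shape[1]
        self.means_, self.precisions_, self.logdets_, self.priors_ = [], [], [], []
        for c in self.classes_:
            Xc = X[y == c]
            mu = Xc.mean(axis=0)
            s = np.cov(Xc, rowvar=False, ddof=1) if len(Xc) > 1 else np.zeros((p, p))
            s = np.atleast_2d(s)
            target = np.trace(s) / p if np.trace(s) > 0 else 1.0
            sigma = (1.0 - self.alpha) * s + self.alpha * target * np.eye(p)
            sign, logdet = np.linalg.slogdet(sigma)
            self.means_.append(mu)
            self.precisions_.append(np.linalg.inv(sigma))
            self.logdets_.append(logdet)
            self.priors_.append(len(Xc) / len(X))
        return self

    def _scores(self, X):
        X = np.asarray(X, dtype=float)
        scores = []
        for mu, prec, logdet, prior in zip(
            self.means_, self.precisions_, self.logdets_, self.priors_
        ):
            d = X - mu
            maha = np.einsum("ij,jk,ik->i", d, prec, d)
            scores.append(-0.5 * (maha + logdet) + np.log(prior))
        return np.column_stack(scores)

    def predict(self, X):
        return self.classes_[np.argmax(self._scores(X), axis=1)]


def make_classifier(classifier_id: str, seed: int = 0):
    rng = int(seed) % (2**31)
    base = {
        "knn": lambda: KNeighborsClassifier(n_neighbors=5),
        "dt": lambda: DecisionTreeClassifier(max_depth=3, random_state=rng),
        "rf": lambda: RandomForestClassifier(
            n_estimators=30, max_depth=3, random_state=rng
        ),
        "adaboost": lambda: AdaBoostClassifier(n_estimators=30, random_state=rng),
        "gboost": lambda: GradientBoostingClassifier(
            n_estimators=30, max_depth=2, random_state=rng
        ),
        "gnb": lambda: GaussianNB(),
        # lsqr + auto shrinkage: well-defined when features outnumber the
        # ~12 samples per class (plain svd LDA refuses that shape)
        "lda": lambda: LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto"),
        "qda": lambda: ShrinkageQDA(alpha=0.5),
        "mlp": lambda: MLPClassifier(
            hidden_layer_sizes=(8,), max_iter=300, tol=1e-3, random_state=rng
        ),
        "lr": lambda: LogisticRegression(max_iter=2000),
    }
    if classifier_id not in base:
        raise ValueError(f"unknown classifier id '{classifier_id}'")
    clf = base[classifier_id]()
    if classifier_id in _SCALED:
        return make_pipeline(StandardScaler(), clf)
    return clf


def balance(labels: pd.Series, seed: int = 0) -> list:
    """All minority-class (pCR) patients plus an equal-size uniform random
    subset of the majority class; deterministic given the seed."""
    pos = labels.index[labels == 1]
    neg = labels.index[labels == 0]
    minority, majority = (pos, neg) if len(pos) <= len(neg) else (neg, pos)
    if len(majority) < len(minority):
        raise ValueError("majority class smaller than minority class")
    if len(majority) == len(minority):
        return list(labels.index)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(majority), size=len(minority), replace=False)
    keep = set(minority) | {majority[i] for i in sorted(chosen)}
    return [pid for pid in labels.index if pid in keep]


def loocv(
    table: pd.DataFrame,
    labels: pd.Series,
    classifier_id: str,
    seed: int = 0,
    fold_hook=None,
):
    """Leave-one-out cross-validation: n folds of test size one.

    Any standardisation lives inside the classifier pipeline and is fitted
    on the n-1 training rows only.  A degenerate single-class training fold
    falls back to predicting that class.  ``fold_hook(fold, train_index)``
    is called per fold for fold-hygiene instrumentation.

    Returns (ConfusionMatrix, per-fold prediction Series).
    """
    if len(table) < 4:
        raise ValueError("LOOCV needs at least 4 cases")
    X = table.to_numpy(dtype=float)
    y = labels.loc[table.index].to_numpy(dtype=int)
    preds = np.empty(len(y), dtype=int)
    for k in range(len(y)):
        train = np.r_[0:k, k + 1 : len(y)]
        if fold_hook is not None:
            fold_hook(k, table.index[train])
        if len(np.unique(y[train])) < 2:
            preds[k] = int(y[train][0])
            continue
        clf = make_classifier(classifier_id, seed)
        clf.fit(X[train], y[train])
        preds[k] = int(clf.predict(X[k : k + 1])[0])
    cm = ConfusionMatrix(
        tp=int(np.sum((preds == 1) & (y == 1))),
        fp=int(np.sum((preds == 1) & (y == 0))),
        fn=int(np.sum((preds == 0) & (y == 1))),
        tn=int(np.sum((preds == 0) & (y == 0))),
    )
    return cm, pd.Series(preds, index=table.index, name="prediction")


def confusion_metrics(cm: ConfusionMatrix) -> ModelMetrics:
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    acc = 100.0 * (cm.tp + cm.tn) / cm.n
    sens = 100.0 * cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) > 0 else None
    spec = 100.0 * cm.tn / (cm.tn + cm.fp) if (cm.tn + cm.fp) > 0 else None
    return ModelMetrics(
        accuracy=acc, sensitivity=sens, specificity=spec, error_rate=100.0 - acc
    )


def _best(cells: dict[str, dict]) -> str:
    """Best classifier by accuracy; ties -> fewer false negatives, then name."""
    return min(
        cells,
        key=lambda cid: (
            -cells[cid]["metrics"].accuracy,
            cells[cid]["confusion"].fn,
            cid,
        ),
    )


def compare_configurations(
    tables: dict[str, pd.DataFrame],
    labels: pd.Series,
    balance_seed: int = 0,
    classifier_seed: int = 0,
    classifiers=CLASSIFIERS,
) -> dict:
    """Balanced LOOCV grid over feature configurations x classifiers.

    ``tables`` maps configuration name (e.g. imaging/clinical/combined) to
    its feature table; all must share the same patients.  Returns a report
    with one confusion matrix + metrics per cell and the best classifier
    per configuration.
    """
    idx = None
    for name, tbl in tables.items():
        if idx is None:
            idx = list(tbl.index)
        elif list(tbl.index) != idx:
            raise ValueError(f"configuration '{name}' has inconsistent patients")
    keep = balance(labels.loc[idx], seed=balance_seed)
    report: dict = {"balance_seed": balance_seed, "patients": keep, "configurations": {}}
    for name, tbl in tables.items():
        sub = tbl.loc[keep]
        cells: dict[str, dict] = {}
        for cid in classifiers:
            cm, _ = loocv(sub, labels, cid, seed=classifier_seed)
            cells[cid] = {"confusion": cm, "metrics": confusion_metrics(cm)}
        report["configurations"][name] = {"cells": cells, "best": _best(cells)}
    return report


def run_study(
    feature_table,
    balance_seed: int = 0,
    classifier_seed: int = 0,
    classifiers=CLASSIFIERS,
    select: bool = True,
    configs: tuple[str, ...] = ("imaging", "clinical", "combined"),
) -> dict:
    """Full modelling protocol on an assembled feature table.

    Balances the cohort, applies the two-step selection to the imaging
    block of the balanced patients, and runs the LOOCV grid over the three
    configurations (imaging / clinical / combined).  Returns the comparison
    report plus the selected feature names.
    """
    from .features import FeatureTable, select_features  # local: avoid cycle

    assert isinstance(feature_table, FeatureTable)
    keep = balance(feature_table.labels, seed=balance_seed)
    imaging = feature_table.imaging.loc[keep]
    clinical = feature_table.clinical.loc[keep]
    if select:
        selection = select_features(imaging)
        imaging = imaging[selection.retained]
    else:
        selection = None
    tables = {
        "imaging": imaging,
        "clinical": clinical,
        "combined": pd.concat([imaging, clinical], axis=1),
    }
    tables = {name: tables[name] for name in configs}
    report = compare_configurations(
        tables, feature_table.labels.loc[keep],
        balance_seed=balance_seed, classifier_seed=classifier_seed,
        classifiers=classifiers,
    )
    report["selected_features"] = list(imaging.columns)
    report["selection"] = selection
    return report


def report_to_frame(report: dict) -> pd.DataFrame:
    """Flatten a comparison report into a tidy metric grid."""
    rows = []
    for cfg, block in report["configurations"].items():
        for cid, cell in block["cells"].items():
            cm, m = cell["confusion"], cell["metrics"]
            rows.append(
                {
                    "configuration": cfg,
                    "classifier": cid,
                    "tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn,
                    "accuracy": m.accuracy,
                    "sensitivity": m.sensitivity,
                    "specificity": m.specificity,
                    "error_rate": m.error_rate,
                    "best": cid == block["best"],
                }
            )
    return pd.DataFrame(rows)
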