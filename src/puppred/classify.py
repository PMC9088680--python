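"""Classifiers, cross-validation, and evaluation metrics.

Five classifier families are supported: random forest, RBF-kernel SVM,
k-nearest-neighbors, gradient-boosted trees (XGBoost), and a stacking
ensemble whose base learners (RF, SVM, KNN) feed a logistic-regression
meta-learner through out-of-fold probability columns.

Evaluation reports sensitivity, specificity, accuracy, the Matthews
correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

and the ROC curve / AUC over all score thresholds.  Cross-validation is
stratified; any balancing, scaling, or feature selection is fitted inside
each training fold only, and the pooled out-of-fold scores produce one
report.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Callable, Optional

import numpy as np
from sklearn.ensemble import RandomForestClassifier, StackingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .encoders import FeatureMatrix
from .select_balance import BalanceConfig, NonnegativeShifter, balance, chi2_scores, select_top_k

logger = logging.getLogger(__name__)

CLASSIFIER_NAMES = ("rf", "svm", "knn", "xgb", "stacking")


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricsReport:
    """Sn/Sp/ACC/MCC plus (optionally) ROC points and AUC."""

    counts: ConfusionCounts
    sn: float
    sp: float
    acc: float
    mcc: float
    auc: Optional[float] = None
    roc_points: Optional[list[tuple[float, float]]] = None

    def to_dict(self) -> dict:
        d = {
            "TP": self.counts.TP,
            "TN": self.counts.TN,
            "FP": self.counts.FP,
            "FN": self.counts.FN,
            "sn": self.sn,
            "sp": self.sp,
            "acc": self.acc,
            "mcc": self.mcc,
        }
        if self.auc is not None:
            d["auc"] = self.auc
        return d

    def to_json(self, path) -> None:
        d = self.to_dict()
        if self.roc_points is not None:
            d["roc_points"] = [[float(a), float(b)] for a, b in self.roc_points]
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, sort_keys=True)


def confusion_from_scores(scores, labels, threshold: float = 0.5) -> ConfusionCounts:
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels, dtype=np.int64)
    pred = (s >= threshold).astype(np.int64)
    return ConfusionCounts(
        TP=int(((pred == 1) & (y == 1)).sum()),
        TN=int(((pred == 0) & (y == 0)).sum()),
        FP=int(((pred == 1) & (y == 0)).sum()),
        FN=int(((pred == 0) & (y == 1)).sum()),
    )


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Sn, Sp, ACC and MCC from a confusion table.

    A zero marginal makes the MCC denominator vanish; the report then
    carries MCC = 0 (logged), the conventional sentinel for an undefined
    correlation.  An empty class likewise yields Sn or Sp = 0.
    """
    if counts.total == 0:
        raise ValueError("compute_metrics: empty confusion table")
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / counts.total
    denom = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    if denom == 0:
        logger.warning("MCC denominator is zero (an empty marginal); reporting MCC=0")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / denom
    return MetricsReport(counts=counts, sn=sn, sp=sp, acc=acc, mcc=mcc)


def roc_auc(scores, labels) -> tuple[list[tuple[float, float]], float]:
    """ROC points (FPR, TPR) over all thresholds and trapezoid-rule AUC.

    Tied scores cross their threshold simultaneously, so ties contribute
    half their mass (all-equal scores give AUC exactly 0.5).
    """
    y = np.asarray(labels, dtype=np.int64)
    if len(np.unique(y)) < 2:
        raise ValueError("roc_auc: both classes must be present")
    fpr, tpr, _ = _sk_roc_curve(y, np.asarray(scores, dtype=np.float64))
    auc = float(np.trapezoid(tpr, fpr))
    return [(float(a), float(b)) for a, b in zip(fpr, tpr)], auc


def full_report(scores, labels, threshold: float = 0.5) -> MetricsReport:
    """Confusion metrics at the threshold plus ROC/AUC from the same scores."""
    rep = compute_metrics(confusion_from_scores(scores, labels, threshold))
    rep.roc_points, rep.auc = roc_auc(scores, labels)
    return rep


# ---------------------------------------------------------------------------
# Classifiers
# ---------------------------------------------------------------------------

@dataclass
class ClassifierSpec:
    """Named classifier plus hyperparameter overrides and a seed.

    Defaults: 500-tree random forest; RBF SVM with probability outputs;
    KNN with k=5; XGBoost with library defaults; stacking over {rf, svm,
    knn} with a logistic-regression meta-learner on 5-fold out-of-fold
    probability columns.
    """

    name: str = "stacking"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in CLASSIFIER_NAMES:
            raise ValueError(f"unknown classifier {self.name!r}; known: {CLASSIFIER_NAMES}")


def _base_learners(seed: int, hp: dict):
    rf = RandomForestClassifier(
        n_estimators=hp.get("rf_trees", 500), random_state=seed, n_jobs=1
    )
    svm = SVC(
        kernel="rbf",
        C=hp.get("svm_C", 1.0),
        gamma=hp.get("svm_gamma", "scale"),
        probability=True,
        random_state=seed,
    )
    knn = KNeighborsClassifier(n_neighbors=hp.get("knn_k", 5))
    return rf, svm, knn


def make_classifier(spec: ClassifierSpec):
    """Build an unfitted scikit-learn-style estimator from a spec."""
    hp = spec.hyperparameters
    rf, svm, knn = _base_learners(spec.seed, hp)
    if spec.name == "rf":
        return rf
    if spec.name == "svm":
        return svm
    if spec.name == "knn":
        return knn
    if spec.name == "xgb":
        return XGBClassifier(
            n_estimators=hp.get("xgb_trees", 100),
            max_depth=hp.get("xgb_depth", 6),
            learning_rate=hp.get("xgb_eta", 0.3),
            random_state=spec.seed,
            n_jobs=1,
            eval_metric="logloss",
        )
    # stacking: out-of-fold predict_proba columns of the three base learners
    # (one column each in the binary case) feed a logistic meta-learner
    return StackingClassifier(
        estimators=[("rf", rf), ("svm", svm), ("knn", knn)],
        final_estimator=LogisticRegression(max_iter=1000, random_state=spec.seed),
        cv=StratifiedKFold(
            n_splits=hp.get("stack_cv", 5), shuffle=True, random_state=spec.seed
        ),
        stack_method="predict_proba",
        n_jobs=1,
    )


def fit_predict(
    spec: ClassifierSpec,
    train: FeatureMatrix,
    train_labels,
    test: FeatureMatrix,
) -> np.ndarray:
    """Fit the spec'd classifier and return positive-class scores for test."""
    if train.feature_names != test.feature_names:
        raise ValueError("fit_predict: train/test feature columns differ")
    y = np.asarray(train_labels, dtype=np.int64)
    if len(np.unique(y)) < 2:
        raise ValueError("fit_predict: training labels must contain both classes")
    clf = make_classifier(spec)
    clf.fit(train.values, y)
    return clf.predict_proba(test.values)[:, 1]


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

FoldFeaturizer = Callable[[np.ndarray, np.ndarray], tuple[FeatureMatrix, FeatureMatrix]]


def cross_validate_indexed(
    spec: ClassifierSpec,
    labels,
    fold_featurizer: FoldFeaturizer,
    *,
    folds: int = 10,
    balance_cfg: Optional[BalanceConfig] = None,
    selection_k: Optional[int] = None,
    seed: int = 0,
    threshold: float = 0.5,
) -> tuple[MetricsReport, np.ndarray]:
    """Stratified k-fold CV where features are built per fold.

    ``fold_featurizer(train_idx, val_idx)`` returns the train/val feature
    matrices for one fold, so that anything fitted on data (embeddings,
    GO-neighbor labels) stays fold-local.  Column shifting, chi-square
    selection, and balancing are likewise fitted on the training fold only.
    Returns the pooled out-of-fold report and the per-sample scores.
    """
    y = np.asarray(labels, dtype=np.int64)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if len(np.unique(y)) < 2:
        raise ValueError("cross_validate: both classes required")
    if min((y == 0).sum(), (y == 1).sum()) < folds:
        raise ValueError(
            f"cross_validate: {folds}-fold stratification impossible with class "
            f"counts {np.bincount(y)}"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    oof = np.full(len(y), np.nan)
    for fold_no, (tr, va) in enumerate(skf.split(np.zeros(len(y)), y)):
        Xtr, Xva = fold_featurizer(tr, va)
        shifter = NonnegativeShifter().fit(Xtr.values)
        Xtr = FeatureMatrix(Xtr.feature_names, shifter.transform(Xtr.values), Xtr.sample_ids)
        Xva = FeatureMatrix(Xva.feature_names, shifter.transform(Xva.values), Xva.sample_ids)
        ytr = y[tr]
        if selection_k is not None:
            sel = chi2_scores(Xtr, ytr)
            Xtr = select_top_k(sel, Xtr, selection_k)
            Xva = select_top_k(sel, Xva, selection_k)
        if balance_cfg is not None and balance_cfg.strategy != "none":
            fold_cfg = BalanceConfig(
                strategy=balance_cfg.strategy,
                target_ratio=balance_cfg.target_ratio,
                rus_ratio=balance_cfg.rus_ratio,
                smote_neighbors=balance_cfg.smote_neighbors,
                seed=balance_cfg.seed + fold_no,
            )
            Xtr, ytr = balance(Xtr, ytr, fold_cfg)
        oof[va] = fit_predict(spec, Xtr, ytr, Xva)
    assert not np.isnan(oof).any(), "every sample must be scored exactly once"
    return full_report(oof, y, threshold), oof


def cross_validate(
    spec: ClassifierSpec,
    features: FeatureMatrix,
    labels,
    folds: int = 10,
    balance_cfg: Optional[BalanceConfig] = None,
    selection_k: Optional[int] = None,
    seed: int = 0,
    threshold: float = 0.5,
) -> MetricsReport:
    """Stratified k-fold CV over a fixed feature matrix (pooled OOF report)."""

    def featurizer(tr, va):
        return features.subset_rows(tr), features.subset_rows(va)

    report, _ = cross_validate_indexed(
        spec,
        labels,
        featurizer,
        folds=folds,
        balance_cfg=balance_cfg,
        selection_k=selection_k,
        seed=seed,
        threshold=threshold,
    )
    return report
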