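"""Linear discriminant classification under stratified k-fold cross-validation.

A two-class Gaussian discriminant with pooled within-class covariance and
empirical priors (classical Fisher LDA).  Folds are stratified so each keeps
the cohort's responder / non-responder proportions; out-of-fold posterior
probabilities are pooled into one confusion matrix (threshold 0.5) and one ROC
curve per experiment, with a DeLong confidence interval on the AUC.  Per-fold
metrics are also reported.

When the pooled covariance is near-singular (small cohorts, correlated
features) a small ridge — 1e-6 * trace/p on the diagonal — is added and the
event is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .selection import delong_auc_ci

log = logging.getLogger(__name__)


@dataclass
class CvConfig:
    k: int = 5
    seed: int = 0
    stratified: bool = True  # always true; kept explicit for the record

    def validate(self, labels: np.ndarray) -> None:
        counts = np.bincount(labels.astype(int), minlength=2)
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if counts.min() < self.k:
            raise ValueError(
                f"smaller class has {counts.min()} members; needs >= k ({self.k})")


@dataclass
class LdaModel:
    means: np.ndarray          # (2, p)
    cov: np.ndarray            # pooled (p, p)
    cov_inv: np.ndarray
    log_priors: np.ndarray     # (2,)
    features: list[str]
    regularized: bool = False


@dataclass
class ClassificationReport:
    sensitivity: float
    specificity: float
    precision: float
    npv: float
    error: float
    accuracy: float
    auc: float
    auc_ci: tuple[float, float]
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    pooled_probabilities: np.ndarray
    pooled_labels: np.ndarray
    per_fold: list[dict] = field(default_factory=list)
    features: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "precision": self.precision, "negative_predictive_value": self.npv,
            "error": self.error, "accuracy": self.accuracy,
            "auc": self.auc, "auc_ci_95": list(self.auc_ci),
            "per_fold": self.per_fold, "features": self.features,
        }


def stratified_folds(labels: np.ndarray, cfg: CvConfig) -> list[np.ndarray]:
    """k disjoint test-index sets covering all rows, class-balanced per fold."""
    labels = np.asarray(labels).astype(int)
    cfg.validate(labels)
    skf = StratifiedKFold(n_splits=cfg.k, shuffle=True, random_state=cfg.seed)
    return [test for _, test in skf.split(np.zeros(len(labels)), labels)]


def lda_fit(x: np.ndarray, y: np.ndarray, features: Optional[Sequence[str]] = None,
            ridge: float = 1e-6) -> LdaModel:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y).astype(int)
    n, p = x.shape
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("LDA here is two-class (responder vs non-responder)")
    if min(np.bincount(y)) < 2:
        raise ValueError("need at least 2 samples per class")
    means = np.stack([x[y == c].mean(axis=0) for c in (0, 1)])
    centered = x - means[y]
    cov = centered.T @ centered / (n - 2)
    regularized = False
    cond = np.linalg.cond(cov)
    if not np.isfinite(cond) or cond > 1e10:
        cov = cov + np.eye(p) * ridge * np.trace(cov) / p
        regularized = True
        cond = np.linalg.cond(cov)
        if not np.isfinite(cond) or cond > 1e14:
            raise np.linalg.LinAlgError(
                "pooled covariance singular even after regularization; "
                f"offending features: {list(features or range(p))}")
        log.info("pooled covariance regularized (ridge %.1e * trace/p)", ridge)
    cov_inv = np.linalg.inv(cov)
    priors = np.bincount(y, minlength=2) / n
    return LdaModel(means, cov, cov_inv, np.log(priors),
                    list(features or [f"x{i}" for i in range(p)]), regularized)


def lda_predict(model: LdaModel, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (predicted class, posterior probability of class 1)."""
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    scores = np.empty((x.shape[0], 2))
    for c in (0, 1):
        mu = model.means[c]
        scores[:, c] = (x @ model.cov_inv @ mu - 0.5 * mu @ model.cov_inv @ mu
                        + model.log_priors[c])
    # stable softmax over the two discriminant scores
    shift = scores.max(axis=1, keepdims=True)
    e = np.exp(scores - shift)
    post1 = e[:, 1] / e.sum(axis=1)
    return (post1 >= 0.5).astype(int), post1


def _confusion_metrics(y: np.ndarray, pred: np.ndarray) -> dict[str, float]:
    tp = int(np.sum((y == 1) & (pred == 1)))
    tn = int(np.sum((y == 0) & (pred == 0)))
    fp = int(np.sum((y == 0) & (pred == 1)))
    fn = int(np.sum((y == 1) & (pred == 0)))

    def pct(num, den):
        return 100.0 * num / den if den else float("nan")

    acc = pct(tp + tn, tp + tn + fp + fn)
    return {
        "sensitivity": pct(tp, tp + fn),
        "specificity": pct(tn, tn + fp),
        "precision": pct(tp, tp + fp),
        "npv": pct(tn, tn + fn),
        "accuracy": acc,
        "error": 100.0 - acc,
    }


def cross_validate(table: pd.DataFrame, labels: pd.Series,
                   features: Optional[Sequence[str]] = None,
                   cfg: Optional[CvConfig] = None,
                   folds: Optional[list[np.ndarray]] = None) -> ClassificationReport:
    """Stratified k-fold LDA; metrics from the pooled out-of-fold confusion
    matrix, ROC/AUC from the pooled posteriors."""
    cfg = cfg or CvConfig()
    features = list(features) if features is not None else list(table.columns)
    x = table[features].to_numpy(dtype=np.float64)
    y = labels.to_numpy().astype(int)
    if folds is None:
        folds = stratified_folds(y, cfg)

    pooled_prob = np.empty(len(y))
    pooled_pred = np.empty(len(y), dtype=int)
    per_fold = []
    for i, test in enumerate(folds):
        train = np.setdiff1d(np.arange(len(y)), test)
        if len(np.unique(y[train])) < 2 or len(np.unique(y[test])) < 1:
            # cannot happen with stratified folds and validated config
            raise RuntimeError("fold with a single class; check configuration")
        model = lda_fit(x[train], y[train], features)
        pred, prob = lda_predict(model, x[test])
        pooled_pred[test] = pred
        pooled_prob[test] = prob
        fold_m = _confusion_metrics(y[test], pred)
        fold_m["fold"] = i
        per_fold.append(fold_m)

    m = _confusion_metrics(y, pooled_pred)
    auc, ci = delong_auc_ci(y, pooled_prob)
    fpr, tpr, _ = roc_curve(y, pooled_prob)
    return ClassificationReport(
        sensitivity=m["sensitivity"], specificity=m["specificity"],
        precision=m["precision"], npv=m["npv"], error=m["error"],
        accuracy=m["accuracy"], auc=auc, auc_ci=ci,
        roc_fpr=fpr, roc_tpr=tpr,
        pooled_probabilities=pooled_prob, pooled_labels=y,
        per_fold=per_fold, features=features,
    )


def compare_feature_sets(table: pd.DataFrame, labels: pd.Series,
                         set_a: Sequence[str], set_b: Sequence[str],
                         cfg: Optional[CvConfig] = None
                         ) -> tuple[ClassificationReport, ClassificationReport]:
    """Cross-validate two feature sets on identical folds (paired contrast,
    e.g. selected features vs all features)."""
    cfg = cfg or CvConfig()
    folds = stratified_folds(labels.to_numpy().astype(int), cfg)
    rep_a = cross_validate(table, labels, set_a, cfg, folds=folds)
    rep_b = cross_validate(table, labels, set_b, cfg, folds=folds)
    return rep_a, rep_b
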