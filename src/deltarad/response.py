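"""LDA classification of therapy response from selected delta features.

A pooled-covariance linear discriminant (shrinkage covariance when the
feature count approaches the cohort size) scores responder vs
non-responder.  Training-cohort performance is the mean AUC over 100
random stratified threefold cross-validation iterations; the held-out
cohort is scored once with the operating threshold frozen from training
(Youden index) and a DeLong 95% CI on the AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

POSITIVE_LABEL = "non-responder"    # progressive disease is the positive class


@dataclass
class LDAModel:
    estimator: LinearDiscriminantAnalysis
    features: list
    threshold: float                  # Youden-index score cutoff from training

    def scores(self, X: pd.DataFrame) -> np.ndarray:
        return self.estimator.decision_function(
            X[self.features].to_numpy(dtype=float))


@dataclass
class ClassifierReport:
    auc: float
    auc_ci: tuple
    accuracy: float
    sensitivity: float
    specificity: float
    threshold: float
    degenerate_scores: bool = False
    cv_trace: list = field(default_factory=list)


def _binary(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "USO":
        return (y == POSITIVE_LABEL).astype(int)
    return y.astype(int)


def train_lda(features: pd.DataFrame, labels) -> LDAModel:
    """Fit the pooled-covariance discriminant and freeze its Youden threshold."""
    y = _binary(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    X = features.to_numpy(dtype=float)
    est = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    est.fit(X, y)
    scores = est.decision_function(X)
    fpr, tpr, thr = roc_curve(y, scores)
    youden = thr[int(np.argmax(tpr - fpr))]
    return LDAModel(est, list(features.columns), float(youden))


def cv_auc(features: pd.DataFrame, labels, folds: int = 3,
           iterations: int = 100, seed: int = 0) -> dict:
    """Mean AUC over repeated random stratified k-fold partitions.

    Each iteration pools the out-of-fold scores into one AUC; the returned
    dict carries the mean, a percentile 95% CI over iterations and the full
    per-iteration trace (length == ``iterations``).
    """
    y = _binary(labels)
    counts = np.bincount(y)
    if counts.min() < folds:
        raise ValueError("a class is too small to stratify across folds")
    X = features.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    trace = []
    for _ in range(iterations):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=int(rng.integers(2 ** 31)))
        scores = np.zeros(len(y))
        for tr, te in skf.split(X, y):
            est = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
            est.fit(X[tr], y[tr])
            scores[te] = est.decision_function(X[te])
        trace.append(float(roc_auc_score(y, scores)))
    trace = list(trace)
    lo, hi = np.percentile(trace, [2.5, 97.5])
    return {"mean_auc": float(np.mean(trace)), "ci": (float(lo), float(hi)),
            "trace": trace}


def delong_ci(scores, y, alpha: float = 0.05):
    """DeLong variance-based CI for the AUC of one classifier."""
    y = np.asarray(y)
    s = np.asarray(scores, dtype=float)
    pos, neg = s[y == 1], s[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        return float("nan"), (float("nan"), float("nan"))
    # placement values via midranks
    all_s = np.concatenate([pos, neg])
    ranks = stats.rankdata(all_s)
    r_pos, r_neg = ranks[:m], ranks[m:]
    auc = (r_pos.sum() - m * (m + 1) / 2) / (m * n)
    v10 = (r_pos - stats.rankdata(pos)) / n          # per-positive placements
    v01 = 1.0 - (r_neg - stats.rankdata(neg)) / m    # per-negative placements
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var)
    return float(auc), (float(np.clip(auc - half, 0, 1)),
                        float(np.clip(auc + half, 0, 1)))


def evaluate_holdout(model: LDAModel, features: pd.DataFrame,
                     labels) -> ClassifierReport:
    """Score a held-out cohort at the training-frozen threshold.

    AUC carries a DeLong 95% CI; a single-class holdout reports AUC as
    missing; constant scores are flagged degenerate (AUC 0.5 by the tie
    convention).
    """
    y = _binary(labels)
    scores = model.scores(features)
    degenerate = bool(np.ptp(scores) == 0)
    if len(np.unique(y)) < 2:
        auc, ci = float("nan"), (float("nan"), float("nan"))
    elif degenerate:
        auc, ci = 0.5, (float("nan"), float("nan"))
    else:
        auc, ci = delong_ci(scores, y)
    pred = (scores >= model.threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return ClassifierReport(
        auc=auc, auc_ci=ci, accuracy=(tp + tn) / len(y),
        sensitivity=sens, specificity=spec, threshold=model.threshold,
        degenerate_scores=degenerate,
    )
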