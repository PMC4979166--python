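"""Binary-classification metrics and the cross-validation harness.

Metrics are the standard confusion-table scores:

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    precision   = TP / (TP + FP)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

plus the area under the ROC curve.  A metric whose denominator is zero is
reported as 0 and flagged rather than raising, since small stratified folds
can legitimately produce degenerate predictions.

``cross_validate`` runs stratified K-fold (default 5) with the *entire*
pipeline — autoencoder pretraining, fine-tuning, base forests and stacking —
refit inside each training fold, so no feature learning ever sees test
labels or test rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .classify import IPMinerClassifier
from .features import build_raw_pair_matrix

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_from_predictions",
    "compute_metrics",
    "compute_auc",
    "cross_validate",
    "cross_validate_scores",
]

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "precision", "mcc", "auc")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    mcc: float
    auc: float | None = None
    degenerate: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        d = {name: getattr(self, name) for name in METRIC_NAMES}
        d["degenerate"] = list(self.degenerate)
        return d


def confusion_from_predictions(y_true, y_pred) -> ConfusionCounts:
    yt = np.asarray(y_true).astype(int).ravel()
    yp = np.asarray(y_pred).astype(int).ravel()
    if yt.shape != yp.shape:
        raise ValueError("y_true and y_pred must be the same length")
    return ConfusionCounts(
        tp=int(np.sum((yt == 1) & (yp == 1))),
        tn=int(np.sum((yt == 0) & (yp == 0))),
        fp=int(np.sum((yt == 0) & (yp == 1))),
        fn=int(np.sum((yt == 1) & (yp == 0))),
    )


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Confusion-table metrics; zero-denominator metrics are 0 and flagged."""
    if c.total == 0:
        raise ValueError("no evaluated pairs")
    flags: list[str] = []

    def safe(num: float, den: float, name: str) -> float:
        if den == 0:
            flags.append(name)
            return 0.0
        return num / den

    tp, tn, fp, fn = float(c.tp), float(c.tn), float(c.fp), float(c.fn)
    accuracy = (tp + tn) / c.total
    sensitivity = safe(tp, tp + fn, "sensitivity")
    specificity = safe(tn, tn + fp, "specificity")
    precision = safe(tp, tp + fp, "precision")
    mcc_den = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = safe(tp * tn - fp * fn, mcc_den, "mcc")
    return MetricsReport(
        accuracy=accuracy, sensitivity=sensitivity, specificity=specificity,
        precision=precision, mcc=mcc, degenerate=flags,
    )


def compute_auc(scores, labels) -> float:
    """Area under the ROC curve (trapezoidal; ties count one half).

    Equals the probability that a random positive outscores a random
    negative, with ties worth 1/2.
    """
    labels = np.asarray(labels).astype(int).ravel()
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires both classes")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float).ravel()))


def cross_validate(
    pairs, protein_seqs, rna_seqs, config=None, k: int = 5,
    seed: int | None = None,
) -> dict:
    """Stratified K-fold cross-validation of the full pipeline.

    Every pair is tested exactly once; the autoencoders, forests and
    stacking layer are refit from scratch on each training fold.  Returns
    ``{"folds": [MetricsReport-dict, ...], "mean": {...}}``.
    """
    # canonical pair order: results do not depend on input file ordering
    pairs = sorted(pairs, key=lambda p: (p[0], p[1], p[2]))
    X = build_raw_pair_matrix(pairs, protein_seqs, rna_seqs)
    y = np.array([p[2] for p in pairs], dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError(f"need at least {k} samples of each class for {k}-fold CV")
    config = dict(config or {})
    base_seed = config.pop("random_state", seed)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_reports = []
    test_index_sets = []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        assert len(set(tr) & set(te)) == 0  # train/test never overlap
        test_index_sets.append(set(te))
        model = IPMinerClassifier(
            **config,
            random_state=None if base_seed is None else base_seed + fold,
        )
        model.fit(X[tr], y[tr])
        probs = model.predict_proba(X[te])[:, 1]
        preds = (probs >= 0.5).astype(int)
        report = compute_metrics(confusion_from_predictions(y[te], preds))
        report.auc = compute_auc(probs, y[te])
        fold_reports.append(report)
    # folds partition the dataset
    union = set().union(*test_index_sets)
    assert union == set(range(len(y)))
    mean = {
        name: float(np.mean([getattr(r, name) for r in fold_reports]))
        for name in METRIC_NAMES
    }
    return {"folds": [r.as_dict() for r in fold_reports], "mean": mean}


def cross_validate_scores(
    pairs, protein_seqs, rna_seqs, config=None, k: int = 5,
    seed: int | None = None,
) -> dict:
    """Per-sample out-of-fold predictions from full-pipeline K-fold CV.

    Like ``cross_validate`` but pools predictions instead of per-fold
    metrics, and also records the three base classifiers' probabilities on
    each test fold so the stacked ensemble can be compared against its
    components on identical held-out data.

    Returns a dict with arrays ``y``, ``ensemble_prob``, ``base_probs``
    (n x 3, columns raw / sda / sda_ft) and ``fold_id``.
    """
    pairs = sorted(pairs, key=lambda p: (p[0], p[1], p[2]))
    X = build_raw_pair_matrix(pairs, protein_seqs, rna_seqs)
    y = np.array([p[2] for p in pairs], dtype=int)
    if np.bincount(y, minlength=2).min() < k:
        raise ValueError(f"need at least {k} samples of each class for {k}-fold CV")
    config = dict(config or {})
    base_seed = config.pop("random_state", seed)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    n = len(y)
    ens = np.zeros(n)
    base = np.zeros((n, 3))
    fold_id = np.full(n, -1, dtype=int)
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        model = IPMinerClassifier(
            **config,
            random_state=None if base_seed is None else base_seed + fold,
        )
        model.fit(X[tr], y[tr])
        ens[te] = model.predict_proba(X[te])[:, 1]
        base[te] = model.base_probabilities(X[te])
        fold_id[te] = fold
    return {"y": y, "ensemble_prob": ens, "base_probs": base, "fold_id": fold_id}
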