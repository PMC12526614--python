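"""Confusion counts, precision/recall/F1/accuracy, ROC/AUC, and the
feature-set comparison report.

The positive class is KI (instability) everywhere: TP = unstable squats
correctly flagged, FN = unstable squats missed. F1 is the binary
(positive-class) F1, not macro-averaged. Accuracy is reported in percent;
report tables round metrics to 2 decimal places.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from . import classify
from .errors import ParameterError
from .features import LabeledDataset
from .select import FeatureSet, make_set

import logging

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class Metrics:
    precision: float
    recall: float
    f1: float
    accuracy_pct: float


def confusion(true: np.ndarray, pred: np.ndarray) -> ConfusionCounts:
    true = np.asarray(true, dtype=int)
    pred = np.asarray(pred, dtype=int)
    if true.shape != pred.shape:
        raise ParameterError("label vectors differ in length")
    return ConfusionCounts(
        tp=int(((true == 1) & (pred == 1)).sum()),
        fp=int(((true == 0) & (pred == 1)).sum()),
        tn=int(((true == 0) & (pred == 0)).sum()),
        fn=int(((true == 1) & (pred == 0)).sum()))


def f1_from_pr(precision: float, recall: float) -> float:
    """Binary F1 = 2PR/(P+R), 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def metrics(c: ConfusionCounts) -> Metrics:
    if c.n == 0:
        raise ParameterError("no evaluated samples")
    if c.tp + c.fp == 0:
        logger.warning("no positive predictions: precision undefined, reported 0")
        precision = 0.0
    else:
        precision = c.tp / (c.tp + c.fp)
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    return Metrics(precision=precision, recall=recall,
                   f1=f1_from_pr(precision, recall),
                   accuracy_pct=100.0 * (c.tp + c.tn) / c.n)


def majority_baseline_accuracy(y: np.ndarray) -> float:
    """Accuracy (%) of always predicting the most frequent class."""
    y = np.asarray(y)
    if y.size == 0:
        raise ParameterError("empty label vector")
    _, counts = np.unique(y, return_counts=True)
    return 100.0 * counts.max() / y.size


def roc_auc(scores: np.ndarray, true: np.ndarray) -> tuple[pd.DataFrame, float]:
    """ROC by sweeping all score thresholds (ties grouped) and trapezoidal AUC.

    The AUC equals the probability that a random positive outscores a random
    negative, ties counted 1/2 (Mann-Whitney statistic).
    """
    scores = np.asarray(scores, dtype=float)
    true = np.asarray(true, dtype=int)
    if scores.shape != true.shape:
        raise ParameterError("scores/labels differ in length")
    n_pos = int((true == 1).sum())
    n_neg = int((true == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ParameterError("ROC requires both classes present")
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    t = true[order]
    # group tied scores: cumulative counts at each distinct-threshold boundary
    distinct = np.concatenate((np.flatnonzero(np.diff(s)) , [s.size - 1]))
    tps = np.cumsum(t)[distinct]
    fps = np.cumsum(1 - t)[distinct]
    tpr = np.concatenate(([0.0], tps / n_pos))
    fpr = np.concatenate(([0.0], fps / n_neg))
    thresholds = np.concatenate(([np.inf], s[distinct]))
    auc = float(np.trapezoid(tpr, fpr))
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return points, auc


def evaluate_predictions(true: np.ndarray, pred: np.ndarray,
                         scores: np.ndarray) -> dict:
    c = confusion(true, pred)
    m = metrics(c)
    _, auc = roc_auc(scores, true)
    return {"auc": auc, "recall": m.recall, "f1": m.f1,
            "precision": m.precision, "accuracy_pct": m.accuracy_pct,
            "tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn}


def stratified_split(dataset: LabeledDataset, train_fraction: float,
                     seed: int) -> tuple[np.ndarray, np.ndarray]:
    idx = np.arange(dataset.n)
    tr, te = train_test_split(idx, train_size=train_fraction,
                              stratify=dataset.y, random_state=seed)
    return np.sort(tr), np.sort(te)


def _subset(dataset: LabeledDataset, idx: np.ndarray) -> LabeledDataset:
    from dataclasses import replace
    return replace(
        dataset, X=dataset.X[idx], y=dataset.y[idx], subjects=dataset.subjects[idx],
        X_phys=None if dataset.X_phys is None else dataset.X_phys[idx],
        summaries=None if dataset.summaries is None
        else dataset.summaries.iloc[idx].reset_index(drop=True),
        truth=None if dataset.truth is None else dataset.truth[idx],
        squat_index=None if dataset.squat_index is None else dataset.squat_index[idx])


def compare_feature_sets(dataset: LabeledDataset, sets: list[FeatureSet],
                         models: tuple[str, ...] = ("lstm", "svm"),
                         cfg: classify.TrainConfig | None = None) -> pd.DataFrame:
    """Train/evaluate every (model, feature set) on one stratified held-out
    split; one report row each, in the given set order."""
    cfg = cfg or classify.TrainConfig()
    tr_idx, te_idx = stratified_split(dataset, cfg.split_fraction, cfg.seed)
    split_desc = f"stratified holdout {cfg.split_fraction:.0%}/{1 - cfg.split_fraction:.0%}"
    rows = []
    for model_name in models:
        for fs in sets:
            sub = make_set(dataset, fs)
            train = _subset(sub, tr_idx)
            test = _subset(sub, te_idx)
            if model_name == "lstm":
                model = classify.train_lstm(train, cfg)
            elif model_name == "svm":
                model = classify.train_svm(train, cfg)
            else:
                raise ParameterError(f"unknown model {model_name!r}")
            scores, pred = classify.predict(model, test)
            res = evaluate_predictions(test.y, pred, scores)
            rows.append({"model": model_name, "feature_sets": fs.name, **res,
                         "split": split_desc, "seed": cfg.seed})
    return pd.DataFrame(rows)


def format_report(report: pd.DataFrame) -> str:
    """Aligned-text table, metrics rounded to 2 dp as in the report convention."""
    cols = ["model", "feature_sets", "auc", "recall", "f1", "precision", "accuracy_pct"]
    out = report[cols].copy()
    for c in ("auc", "recall", "f1", "precision", "accuracy_pct"):
        out[c] = out[c].map(lambda v: f"{v:.2f}")
    return out.to_string(index=False)
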