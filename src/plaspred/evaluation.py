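"""Cross-validation harness, classification metrics and ROC analysis.

Performance of the binary models is summarised with accuracy,
sensitivity, specificity (all in percent) and the Matthews correlation
coefficient:

    ACC = (TP + TN) / (TP + TN + FP + FN) * 100
    SN  = TP / (TP + FN) * 100
    SP  = TN / (TN + FP) * 100
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

Cross-validation follows the five-fold protocol: the dataset is randomly
partitioned into five near-equal sets, each used once for testing while
the other four train, and the reported figures are the unweighted mean
of the per-fold metric sets (pooled counts are retained for inspection).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .seqio import LabeledDataset, POSITIVE_LABELS, ValidationError
from .features import encode_dataset
from .model import (
    LEVEL1,
    PgActivatorModel,
    SUBCLASS_ORDER,
    SVMConfig,
    default_params,
    train,
)


@dataclass(frozen=True)
class FoldSplit:
    """A k-fold partition: fold index in [0, k) for each dataset item."""

    assignments: np.ndarray
    k: int
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts."""

    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class MetricSet:
    """ACC/SN/SP in percent and MCC in [-1, 1]; NaN marks undefined."""

    accuracy: float
    sensitivity: float
    specificity: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return {"ACC": self.accuracy, "SN": self.sensitivity,
                "SP": self.specificity, "MCC": self.mcc}


@dataclass(frozen=True)
class ROCCurve:
    """Ordered (FPR, TPR) points and the trapezoidal area under them."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def make_folds(n: int, k: int = 5, seed: int = 0,
               stratify_labels: Sequence | None = None) -> FoldSplit:
    """Seeded shuffle followed by round-robin fold assignment.

    With `stratify_labels`, shuffling and round-robin assignment happen
    within each label group; a rolling fold counter carries across
    groups so overall fold sizes still differ by at most one.
    """
    if n < k:
        raise ValidationError(f"cannot make {k} folds from {n} items")
    if k < 2:
        raise ValidationError("k must be >= 2")
    rng = np.random.default_rng(seed)
    assignments = np.empty(n, dtype=int)
    if stratify_labels is None:
        order = rng.permutation(n)
        assignments[order] = np.arange(n) % k
    else:
        labels = np.asarray(stratify_labels)
        if labels.shape[0] != n:
            raise ValidationError("stratify_labels length must equal n")
        counter = 0
        for lab in pd.unique(labels):
            idx = np.flatnonzero(labels == lab)
            idx = rng.permutation(idx)
            for i in idx:
                assignments[i] = counter % k
                counter += 1
    return FoldSplit(assignments=assignments, k=k, seed=seed)


def metrics(cm: ConfusionMatrix) -> MetricSet:
    """Accuracy, sensitivity, specificity (percent) and MCC from counts.

    A metric whose defining marginal is zero is reported as NaN
    (undefined) with a warning rather than silently as 0.
    """
    tp, fp, tn, fn = cm.TP, cm.FP, cm.TN, cm.FN
    total = cm.total
    acc = 100.0 * (tp + tn) / total if total else math.nan
    if tp + fn > 0:
        sn = 100.0 * tp / (tp + fn)
    else:
        warnings.warn("no positive examples: sensitivity undefined",
                      stacklevel=2)
        sn = math.nan
    if tn + fp > 0:
        sp = 100.0 * tn / (tn + fp)
    else:
        warnings.warn("no negative examples: specificity undefined",
                      stacklevel=2)
        sp = math.nan
    denom = ((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom > 0:
        mcc = (tp * tn - fp * fn) / math.sqrt(denom)
    else:
        warnings.warn("a confusion marginal is zero: MCC undefined",
                      stacklevel=2)
        mcc = math.nan
    return MetricSet(accuracy=acc, sensitivity=sn, specificity=sp, mcc=mcc)


def confusion_from_predictions(y_true: Sequence[int],
                               y_pred: Sequence[int]) -> ConfusionMatrix:
    """Binary counts from +/-1 truth and prediction arrays."""
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    return ConfusionMatrix(
        TP=int(np.sum((yt == 1) & (yp == 1))),
        FP=int(np.sum((yt == -1) & (yp == 1))),
        TN=int(np.sum((yt == -1) & (yp == -1))),
        FN=int(np.sum((yt == 1) & (yp == -1))),
    )


def confusion_table(true_labels: Sequence[str],
                    predicted_labels: Sequence[str]) -> pd.DataFrame:
    """Multiclass confusion table: rows are true, columns predicted."""
    if len(true_labels) != len(predicted_labels):
        raise ValidationError("label lists differ in length")
    rows = list(dict.fromkeys(true_labels))
    cols = list(dict.fromkeys(list(predicted_labels) + rows))
    table = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        table.loc[t, p] += 1
    table.index.name = "true"
    table.columns.name = "predicted"
    return table


def roc(scores: Sequence[float], labels: Sequence[int]) -> ROCCurve:
    """ROC curve and trapezoidal AUC from decision scores.

    Thresholds sweep the unique scores in descending order; tied scores
    collapse into a single step, so the curve (and its area) match the
    rank statistic P(score+ > score-) + P(tie)/2.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValidationError("scores and labels differ in length")
    if len(np.unique(y)) < 2:
        raise ValidationError("ROC needs both classes present")
    fpr, tpr, thr = _sk_roc_curve(y, s, pos_label=1,
                                  drop_intermediate=False)
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thr,
                    auc=float(_sk_auc(fpr, tpr)))


@dataclass
class CrossValidationResult:
    """Per-fold and averaged binary CV metrics."""

    mean: MetricSet
    folds: list[MetricSet]
    fold_matrices: list[ConfusionMatrix]
    pooled: ConfusionMatrix
    split: FoldSplit

    def frame(self) -> pd.DataFrame:
        rows = [dict(fold=i, **m.as_dict())
                for i, m in enumerate(self.folds)]
        rows.append(dict(fold="mean", **self.mean.as_dict()))
        return pd.DataFrame(rows)


def _mean_metrics(folds: list[MetricSet]) -> MetricSet:
    def nm(vals):
        arr = np.array(vals, dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return float(np.nanmean(arr))
    return MetricSet(
        accuracy=nm([m.accuracy for m in folds]),
        sensitivity=nm([m.sensitivity for m in folds]),
        specificity=nm([m.specificity for m in folds]),
        mcc=nm([m.mcc for m in folds]),
    )


def cross_validate(dataset: LabeledDataset, method: str = "DC",
                   params: Mapping[str, tuple[float, float]] | None = None,
                   seed: int = 0, k: int = 5, stratify: bool = False,
                   **pssm_kwargs) -> CrossValidationResult:
    """k-fold CV of the level-1 activator-vs-non gate.

    Positives are all four subfamilies pooled, negatives the NEG class.
    Each fold trains a fresh RBF SVM at the method's (gamma, C) defaults
    (or `params[LEVEL1]`) on the other folds and scores the held-out
    fold at threshold 0.
    """
    all_params = default_params(method)
    if params:
        all_params.update(params)
    gamma, cost = all_params[LEVEL1]
    cfg = SVMConfig(gamma=gamma, cost=cost, feature_method=method)

    y = np.where(np.isin(np.array(dataset.labels), POSITIVE_LABELS), 1, -1)
    X = encode_dataset(dataset, method, **pssm_kwargs)
    split = make_folds(len(dataset), k=k, seed=seed,
                       stratify_labels=dataset.labels if stratify else None)

    fold_metrics: list[MetricSet] = []
    fold_cms: list[ConfusionMatrix] = []
    for fold in range(k):
        tr, te = split.train_indices(fold), split.test_indices(fold)
        if len(np.unique(y[tr])) < 2:
            raise ValidationError(
                f"fold {fold} training data has a single class; "
                "use stratify=True"
            )
        m = train(X[tr], y[tr], cfg)
        pred = np.where(m.decision(X[te]) >= 0, 1, -1)
        cm = confusion_from_predictions(y[te], pred)
        fold_cms.append(cm)
        fold_metrics.append(metrics(cm))
    pooled = ConfusionMatrix(
        TP=sum(c.TP for c in fold_cms), FP=sum(c.FP for c in fold_cms),
        TN=sum(c.TN for c in fold_cms), FN=sum(c.FN for c in fold_cms))
    return CrossValidationResult(mean=_mean_metrics(fold_metrics),
                                 folds=fold_metrics, fold_matrices=fold_cms,
                                 pooled=pooled, split=split)


@dataclass
class HierarchicalCVResult:
    """Cross-validated two-stage predictions and their confusion table."""

    confusion: pd.DataFrame
    predictions: pd.DataFrame
    accuracy: float
    level1: CrossValidationResult | None = None


def cross_validate_hierarchical(
        dataset: LabeledDataset, method: str = "DC",
        params: Mapping[str, tuple[float, float]] | None = None,
        seed: int = 0, k: int = 5, threshold: float = 0.0,
        stratify: bool = True, **pssm_kwargs) -> HierarchicalCVResult:
    """k-fold CV of the full two-stage pipeline.

    Within each fold a complete five-model bundle is trained on the
    other folds and the held-out sequences run through the gate-then-
    subclass prediction; a NON_PG call maps to the NEG label.  Returns
    the multiclass confusion table (rows true, columns predicted), the
    per-sequence prediction table, and the overall label accuracy.

    Stratified folds are the default here: the smallest subfamily may
    otherwise vanish from a training fold entirely.
    """
    split = make_folds(len(dataset), k=k, seed=seed,
                       stratify_labels=dataset.labels if stratify else None)
    recs = []
    for fold in range(k):
        tr = split.train_indices(fold)
        te = split.test_indices(fold)
        bundle = PgActivatorModel(dataset.subset(tr), method,
                                  params=params, **pssm_kwargs).fit()
        results = bundle.predict([dataset.sequences[i] for i in te],
                                 threshold=threshold)
        for i, r in zip(te, results):
            pred = r.subclass_call if r.level1_call == "PG" else "NEG"
            recs.append({"id": r.sequence_id, "fold": fold,
                         "true": dataset.labels[i], "predicted": pred,
                         "level1_score": r.level1_score})
    preds = pd.DataFrame(recs)
    order = [lab for lab in (*SUBCLASS_ORDER, "NEG")
             if lab in set(preds["true"]) | set(preds["predicted"])]
    table = confusion_table(list(preds["true"]), list(preds["predicted"]))
    table = table.reindex(index=[r for r in order if r in table.index],
                          columns=order, fill_value=0)
    acc = float(np.mean(preds["true"] == preds["predicted"]))
    return HierarchicalCVResult(confusion=table, predictions=preds,
                                accuracy=acc)
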