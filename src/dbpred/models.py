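"""Classifiers, validation schemes and binary-classification metrics.

The default classifier is a soft-margin SVM with the Gaussian kernel
``K(x1, x2) = exp(-||x1 - x2||^2 / (2 sigma^2))``; a random forest is
available for comparison. Features are standardised with training-set
statistics before the SVM, since a Gaussian kernel over heterogeneous
feature scales is dominated by the widest columns.

Evaluation follows the three schemes common in protein-classification
studies: stratified k-fold cross-validation (accuracy averaged over folds),
jackknife (leave-one-out predictions pooled into one confusion matrix) and
a held-out stratified test split. The report carries sensitivity,
specificity, accuracy and Matthews correlation coefficient:

    SN  = TP / (TP + FN)
    SP  = TN / (TN + FP)
    ACC = (TP + TN) / (TP + FP + TN + FN)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with MCC defined as 0 when any factor of the denominator vanishes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io_formats import FeatureMatrix, LabeledDataset


@dataclass(frozen=True)
class KernelParams:
    """Gaussian-kernel width ``sigma`` and soft-margin penalty ``C``.

    ``sigma=None`` applies the heuristic ``sigma = sqrt(d/2)`` for d
    features, i.e. kernel coefficient ``gamma = 1/d`` on standardised data.
    """

    sigma: float | None = None
    c_penalty: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.c_penalty <= 0:
            raise ValueError("C must be positive")

    def resolved_sigma(self, n_features: int) -> float:
        return self.sigma if self.sigma is not None else math.sqrt(n_features / 2.0)


@dataclass(frozen=True)
class ModelSpec:
    """Which classifier to train and with what hyperparameters."""

    kind: str = "svm"
    kernel: KernelParams = field(default_factory=KernelParams)
    n_trees: int = 500

    def __post_init__(self) -> None:
        if self.kind not in {"svm", "random_forest", "rf"}:
            raise ValueError(f"unknown classifier kind {self.kind!r}")


@dataclass
class TrainedModel:
    """A fitted classifier bound to the feature names it was trained on."""

    kind: str
    params: dict[str, Any]
    pipeline: Pipeline
    feature_names: list[str]


@dataclass(frozen=True)
class EvaluationReport:
    """Confusion counts and the four derived metrics."""

    tp: int
    fp: int
    tn: int
    fn: int
    sn: float
    sp: float
    acc: float
    mcc: float

    def to_dict(self) -> dict[str, float]:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "sn": self.sn, "sp": self.sp, "acc": self.acc, "mcc": self.mcc,
        }


def gaussian_kernel(x1: np.ndarray, x2: np.ndarray, sigma: float) -> float:
    """``exp(-||x1 - x2||^2 / (2 sigma^2))``; symmetric, in (0, 1]."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape:
        raise ValueError(f"dimension mismatch: {x1.shape} vs {x2.shape}")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    d2 = float(np.sum((x1 - x2) ** 2))
    return math.exp(-d2 / (2.0 * sigma * sigma))


def _build_pipeline(spec: ModelSpec, n_features: int, seed: int) -> Pipeline:
    if spec.kind in {"random_forest", "rf"}:
        clf = RandomForestClassifier(
            n_estimators=spec.n_trees, random_state=seed, n_jobs=1
        )
        return Pipeline([("clf", clf)])
    sigma = spec.kernel.resolved_sigma(n_features)
    clf = SVC(
        kernel="rbf",
        gamma=1.0 / (2.0 * sigma * sigma),
        C=spec.kernel.c_penalty,
        random_state=seed,
    )
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def train_classifier(
    ds: LabeledDataset, spec: ModelSpec | None = None, seed: int = 0
) -> TrainedModel:
    """Fit the configured classifier; deterministic for a given seed."""
    spec = spec or ModelSpec()
    if len(np.unique(ds.labels)) < 2:
        raise ValueError("training requires both classes present")
    pipeline = _build_pipeline(spec, ds.features.n_features, seed)
    pipeline.fit(ds.features.values, ds.labels)
    params: dict[str, Any] = {"kind": spec.kind, "seed": seed}
    if spec.kind == "svm":
        params["sigma"] = spec.kernel.resolved_sigma(ds.features.n_features)
        params["C"] = spec.kernel.c_penalty
    else:
        params["n_trees"] = spec.n_trees
    return TrainedModel(
        kind=spec.kind,
        params=params,
        pipeline=pipeline,
        feature_names=list(ds.features.feature_names),
    )


def predict(model: TrainedModel, fm: FeatureMatrix) -> np.ndarray:
    """Predict one binary label per row; columns must match training."""
    if fm.feature_names != model.feature_names:
        missing = sorted(set(model.feature_names) - set(fm.feature_names))
        extra = sorted(set(fm.feature_names) - set(model.feature_names))
        raise ValueError(
            f"feature mismatch: missing {missing[:5]}, extra {extra[:5]}"
            if missing or extra
            else "feature columns are ordered differently than at training"
        )
    if fm.n_samples == 0:
        return np.empty(0, dtype=int)
    return model.pipeline.predict(fm.values).astype(int)


def save_model(model: TrainedModel, path: str | Path) -> None:
    joblib.dump({"format_version": 1, "model": model}, path)


def load_model(path: str | Path) -> TrainedModel:
    payload = joblib.load(path)
    if payload.get("format_version") != 1:
        raise ValueError("unrecognized model file version")
    return payload["model"]


def compute_metrics(tp: int, fp: int, tn: int, fn: int) -> EvaluationReport:
    """SN, SP, ACC and MCC from raw confusion counts."""
    counts = (tp, fp, tn, fn)
    if any(c < 0 for c in counts):
        raise ValueError("confusion counts must be non-negative")
    total = sum(counts)
    if total == 0:
        raise ValueError("confusion counts are all zero")
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / total
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = ((tp * tn) - (fp * fn)) / math.sqrt(denom) if denom else 0.0
    return EvaluationReport(tp=tp, fp=fp, tn=tn, fn=fn, sn=sn, sp=sp, acc=acc, mcc=mcc)


def metrics_from_predictions(
    y_true: np.ndarray, y_pred: np.ndarray
) -> EvaluationReport:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return compute_metrics(tp, fp, tn, fn)


def k_fold_cv(
    ds: LabeledDataset,
    k: int = 10,
    spec: ModelSpec | None = None,
    seed: int = 0,
) -> tuple[float, list[EvaluationReport]]:
    """Stratified k-fold cross-validation.

    Returns the mean of the per-fold accuracies together with the per-fold
    reports. Fold assignment is shuffled deterministically by ``seed``.
    """
    spec = spec or ModelSpec()
    if k < 2:
        raise ValueError("k must be >= 2")
    n = ds.n_samples
    class_counts = np.bincount(ds.labels, minlength=2)
    if class_counts.min() < 1:
        raise ValueError("both classes must be present")
    if k == n:
        # fold size 1: stratification is vacuous and this is leave-one-out
        splits = [(np.delete(np.arange(n), i), np.array([i])) for i in range(n)]
    elif class_counts.min() < k:
        raise ValueError(
            f"smallest class has {class_counts.min()} samples; cannot form {k} folds"
        )
    else:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = list(skf.split(ds.features.values, ds.labels))
    reports = []
    for train_idx, test_idx in splits:
        model = train_classifier(ds.subset(train_idx), spec, seed=seed)
        pred = predict(model, ds.subset(test_idx).features)
        reports.append(metrics_from_predictions(ds.labels[test_idx], pred))
    mean_acc = float(np.mean([r.acc for r in reports]))
    return mean_acc, reports


def jackknife_cv(
    ds: LabeledDataset, spec: ModelSpec | None = None, seed: int = 0
) -> EvaluationReport:
    """Leave-one-out validation pooled into a single confusion matrix."""
    spec = spec or ModelSpec()
    n = ds.n_samples
    if n < 3:
        raise ValueError("jackknife needs at least 3 samples")
    preds = np.empty(n, dtype=int)
    all_idx = np.arange(n)
    for i in range(n):
        train_idx = all_idx[all_idx != i]
        model = train_classifier(ds.subset(train_idx), spec, seed=seed)
        preds[i] = predict(model, ds.subset(np.array([i])).features)[0]
    return metrics_from_predictions(ds.labels, preds)


def train_test_split_stratified(
    ds: LabeledDataset, train_fraction: float = 0.8, seed: int = 0
) -> tuple[LabeledDataset, LabeledDataset]:
    """Class-balance-preserving random split.

    The training set holds ``floor(fraction * n)`` samples, allocated to the
    classes proportionally (largest fractional remainder first), so a
    balanced 186-sample set at 0.8 yields 74+74 training and 19+19 test.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    classes = np.unique(ds.labels)
    counts = {cls: int(np.sum(ds.labels == cls)) for cls in classes}
    n = ds.n_samples
    n_train = int(math.floor(train_fraction * n))
    quotas = {cls: n_train * counts[cls] / n for cls in classes}
    alloc = {cls: int(math.floor(quotas[cls])) for cls in classes}
    leftover = n_train - sum(alloc.values())
    for cls in sorted(classes, key=lambda c: (-(quotas[c] - alloc[c]), c)):
        if leftover == 0:
            break
        alloc[cls] += 1
        leftover -= 1
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in classes:
        members = np.flatnonzero(ds.labels == cls)
        k = alloc[cls]
        if k == 0 or k == len(members):
            raise ValueError(
                f"class {cls} would be emptied by a {train_fraction:.0%} split"
            )
        perm = rng.permutation(members)
        train_idx.extend(perm[:k])
        test_idx.extend(perm[k:])
    train_idx_arr = np.sort(np.array(train_idx))
    test_idx_arr = np.sort(np.array(test_idx))
    return ds.subset(train_idx_arr), ds.subset(test_idx_arr)
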