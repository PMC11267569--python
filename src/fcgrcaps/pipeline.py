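"""Training, tuning, evaluation and two-stage prediction.

Metrics follow the standard binary-classification suite: accuracy,
sensitivity TP/(TP+FN), specificity TN/(TN+FP), the Matthews correlation
coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

and AUC as the Mann-Whitney probability that a random positive outscores a
random negative (ties counted 1/2), using the positive capsule length as the
score.  A metric whose denominator is zero is reported as None, never as 0.

Percentages are reported on the 0-100 scale (ACC/SN/SP/AUC); MCC on [-1, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .estimators import CapsNetClassifier, infer_positive_label

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "UndefinedMetricError",
    "compute_metrics",
    "auc_score",
    "stratified_kfold",
    "train_model",
    "grid_search",
    "evaluate",
    "TwoStageModel",
    "predict_two_stage",
    "export_embeddings",
]


class UndefinedMetricError(ValueError):
    """A metric's denominator is zero (e.g. AUC with one class present)."""


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    """ACC/SN/SP as percentages, MCC in [-1, 1], AUC as a percentage.

    Undefined entries (zero denominator) are None.
    """

    confusion: ConfusionMatrix
    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    mcc: float | None
    auc: float | None = None

    def to_dict(self) -> dict:
        return {"tp": self.confusion.tp, "tn": self.confusion.tn,
                "fp": self.confusion.fp, "fn": self.confusion.fn,
                "accuracy": self.accuracy, "sensitivity": self.sensitivity,
                "specificity": self.specificity, "mcc": self.mcc, "auc": self.auc}


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Evaluate ACC/SN/SP/MCC from a confusion matrix (AUC needs scores and
    is attached by :func:`evaluate`)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    tp, tn, fp, fn = cm.tp, cm.tn, cm.fp, cm.fn
    acc = 100.0 * (tp + tn) / cm.total
    sn = 100.0 * tp / (tp + fn) if tp + fn else None
    sp = 100.0 * tn / (tn + fp) if tn + fp else None
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else None
    return MetricsReport(cm, acc, sn, sp, mcc)


def auc_score(scores, labels) -> float:
    """Mann-Whitney AUC in [0, 1]: fraction of positive-negative pairs
    ordered correctly, ties counted 1/2.  ``labels`` are binary (1 =
    positive)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    if np.unique(labels).shape[0] < 2:
        raise UndefinedMetricError("AUC is undefined with a single class present")
    return float(roc_auc_score(labels, scores))


def stratified_kfold(labels, k: int = 5, seed: int = 0) -> list[np.ndarray]:
    """Deterministic stratified partition into ``k`` disjoint test folds
    (returned as index arrays).  Requires at least ``k`` records per class."""
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"need >= {k} records per class, got counts {counts.tolist()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test_idx for _, test_idx in skf.split(np.zeros(len(labels)), labels)]


def train_model(X, y, config="small", n_epochs: int = 100, batch_size: int = 32,
                learning_rate: float = 1e-3, seed: int = 0,
                estimator_cls=CapsNetClassifier, positive_label=None):
    """Fit a classifier on labeled FCGR images; returns ``(estimator,
    loss_curve)``.  Thin functional wrapper over the estimator API.  When
    ``positive_label`` is None it is inferred from the domain label set
    (enhancer > nonenhancer, strong > weak)."""
    if positive_label is None:
        positive_label = infer_positive_label(y)
    clf = estimator_cls(config=config, n_epochs=n_epochs, batch_size=batch_size,
                        learning_rate=learning_rate, random_state=seed,
                        positive_label=positive_label)
    clf.fit(X, y)
    return clf, list(clf.loss_curve_)


def grid_search(X, y, grid: dict[str, list], k: int = 5, seed: int = 0,
                estimator_cls=CapsNetClassifier, base_params: dict | None = None):
    """Exhaustive grid search scored by mean stratified-CV accuracy.

    ``grid`` maps estimator parameter names (e.g. ``learning_rate``,
    ``n_epochs``, ``batch_size``) to candidate lists.  Ties break toward the
    earlier combination in Cartesian-product order (axes in ``grid``'s key
    order).  A combination that fails to construct or diverges is recorded
    with a None score and an error message rather than aborting the search.

    Returns ``(best_params, table)`` where ``table`` is one row per
    combination with its per-fold and mean accuracies.
    """
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("grid must have at least one non-empty axis")
    y = np.asarray(y)
    folds = stratified_kfold(y, k=k, seed=seed)
    all_idx = np.arange(len(y))
    rows = []
    best = None  # (score, order_index, params)
    keys = list(grid.keys())
    for order_i, combo in enumerate(product(*(grid[k_] for k_ in keys))):
        params = dict(zip(keys, combo))
        fold_accs, err = [], None
        try:
            for fold_idx, test_idx in enumerate(folds):
                train_idx = np.setdiff1d(all_idx, test_idx)
                clf = estimator_cls(random_state=seed, **(base_params or {}), **params)
                clf.fit(X[train_idx], y[train_idx])
                fold_accs.append(float(np.mean(clf.predict(X[test_idx]) == y[test_idx])))
        except (ValueError, RuntimeError) as e:
            err = str(e)
        mean_acc = float(np.mean(fold_accs)) if err is None else None
        rows.append({**params, "mean_cv_accuracy": mean_acc,
                     "fold_accuracies": fold_accs if err is None else None,
                     "error": err})
        if mean_acc is not None and (best is None or mean_acc > best[0]):
            best = (mean_acc, order_i, params)
    table = pd.DataFrame(rows)
    if best is None:
        raise ValueError("every grid combination failed:\n" + table.to_string())
    return best[2], table


def evaluate(clf, X, y, positive_label=None, train_ids=None, test_ids=None) -> MetricsReport:
    """Score a fitted classifier on a labeled test set.

    The positive class defaults to ``clf.classes_[1]``.  AUC uses the
    positive capsule length as the score.  If both ``train_ids`` and
    ``test_ids`` are given, an id overlap raises a warning (test-set
    disjointness is the caller's responsibility).
    """
    if train_ids is not None and test_ids is not None:
        overlap = set(train_ids) & set(test_ids)
        if overlap:
            warnings.warn(f"{len(overlap)} test ids overlap the training set "
                          f"(e.g. {sorted(overlap)[:3]})", stacklevel=2)
    y = np.asarray(y)
    pos = clf.classes_[1] if positive_label is None else positive_label
    pred = clf.predict(X)
    yb = y == pos
    pb = pred == pos
    cm = ConfusionMatrix(tp=int(np.sum(yb & pb)), tn=int(np.sum(~yb & ~pb)),
                         fp=int(np.sum(~yb & pb)), fn=int(np.sum(yb & ~pb)))
    report = compute_metrics(cm)
    scores = clf.predict_lengths(X)[:, list(clf.classes_).index(pos)]
    try:
        report.auc = 100.0 * auc_score(scores, yb.astype(int))
    except UndefinedMetricError:
        report.auc = None
    return report


@dataclass
class TwoStageModel:
    """Stage-1 (enhancer vs nonenhancer) and stage-2 (strong vs weak)
    classifiers sharing one FCGR representation (same N and input scaling)."""

    stage1: CapsNetClassifier
    stage2: CapsNetClassifier | None = None
    resolution: int = 64

    def __post_init__(self):
        if self.stage2 is not None:
            r1 = getattr(self.stage1, "config_", None)
            r2 = getattr(self.stage2, "config_", None)
            if r1 and r2 and (r1.input_resolution != r2.input_resolution
                              or r1.input_scaling != r2.input_scaling):
                raise ValueError("both stages must share the FCGR resolution and scaling")


def predict_two_stage(model: TwoStageModel, X, ids=None, mode: str = "chained") -> pd.DataFrame:
    """Run the two-stage decision over encoded records.

    ``chained`` (deployment semantics) runs stage 2 only on stage-1
    positives; ``independent`` (benchmark semantics) scores every record with
    both stages.  Stage-1 outputs are identical between modes.  Returns a
    frame with columns id, p_enhancer, stage1_call, p_strong, stage2_call.
    """
    if mode not in ("chained", "independent"):
        raise ValueError(f"mode must be 'chained' or 'independent', got {mode!r}")
    if model.stage2 is None:
        raise ValueError("two-stage prediction requires a fitted stage-2 model")
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    ids = list(ids) if ids is not None else [f"rec_{i}" for i in range(n)]

    s1 = model.stage1
    p1 = s1.predict_lengths(X)
    pos1 = list(s1.classes_).index(s1.classes_[1])
    call1 = s1.predict(X)
    p_enh = p1[:, pos1]

    s2 = model.stage2
    pos2_label = s2.classes_[1]
    p_strong = np.full(n, np.nan)
    call2 = np.array([None] * n, dtype=object)
    if mode == "independent":
        sel = np.arange(n)
    else:
        sel = np.flatnonzero(call1 == s1.classes_[1])
    if sel.size:
        p2 = s2.predict_lengths(X[sel])
        p_strong[sel] = p2[:, list(s2.classes_).index(pos2_label)]
        call2[sel] = s2.predict(X[sel])
    return pd.DataFrame({"id": ids, "p_enhancer": p_enh, "stage1_call": call1,
                         "p_strong": p_strong, "stage2_call": call2})


def export_embeddings(clf, X, layer: str = "type", ids=None) -> pd.DataFrame:
    """Per-record feature table from a trained model.

    ``layer='primary'`` flattens the L primary-capsule activities (L*m
    columns); ``layer='type'`` concatenates the two type-capsule vectors
    (2*n columns).  One row per record, indexed by id.
    """
    if layer not in ("primary", "type"):
        raise ValueError(f"layer must be 'primary' or 'type', got {layer!r}")
    out = clf.forward_details(np.asarray(X, dtype=np.float64))
    if layer == "primary":
        feats = out["u"].reshape(out["u"].shape[0], -1)
    else:
        if out["V"] is None:
            raise ValueError("this model has no type-capsule layer")
        feats = out["V"].reshape(out["V"].shape[0], -1)
    ids = list(ids) if ids is not None else [f"rec_{i}" for i in range(feats.shape[0])]
    df = pd.DataFrame(feats, columns=[f"f{i}" for i in range(feats.shape[1])])
    df.insert(0, "id", ids)
    return df
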