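"""Training/evaluation workflow: stratified folds, nested cross-validation
with ensemble averaging, external-cohort ensembling and class-balanced
bootstrap metrics.

The nested scheme: the cohort is split into five stage-stratified folds.
For each test fold, four models are trained — one per rotation of the
validation fold through the remaining folds (train on three, validate on
one) — and their class-1 probabilities on the test fold are averaged.
Stacking the five test folds gives exactly one internal prediction per
patient and 5 x 4 = 20 fitted models, which are then ensemble-averaged on
any external cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .models import PROBABILITY_THRESHOLD

logger = logging.getLogger(__name__)

METRIC_NAMES = ("accuracy", "auc", "mcc_scaled", "f1_class1", "f1_class0",
                "precision", "recall", "specificity")


@dataclass(frozen=True)
class FoldPlan:
    patient_ids: tuple
    fold_index: np.ndarray          # per patient, 0..k-1
    strata: np.ndarray
    seed: int

    @property
    def k(self) -> int:
        return int(self.fold_index.max()) + 1

    def fold_members(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index == fold)


@dataclass
class PredictionSet:
    patient_ids: list
    probabilities: np.ndarray

    def __post_init__(self):
        self.probabilities = np.asarray(self.probabilities, dtype=np.float64)
        if np.any((self.probabilities < 0) | (self.probabilities > 1)):
            raise ValueError("probabilities must lie in [0, 1]")
        if len(self.patient_ids) != len(self.probabilities):
            raise ValueError("ids and probabilities length mismatch")

    @property
    def labels(self) -> np.ndarray:
        return (self.probabilities >= PROBABILITY_THRESHOLD).astype(int)


def make_folds(patient_ids, strata, k: int = 5, seed: int = 0) -> FoldPlan:
    """Stratified partition into k folds, deterministic under seed."""
    patient_ids = tuple(patient_ids)
    strata = np.asarray(strata)
    for value, count in zip(*np.unique(strata, return_counts=True)):
        if count < k:
            raise ValueError(f"stratum {value!r} has only {count} members (< k={k})")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_index = np.empty(len(patient_ids), dtype=int)
    for fold, (_tr, test) in enumerate(splitter.split(np.zeros(len(patient_ids)), strata)):
        fold_index[test] = fold
    return FoldPlan(patient_ids, fold_index, strata, seed)


def nested_cv_train(model_factory, X, y, fold_plan: FoldPlan,
                    preprocess=None):
    """The repeated nested-CV workflow: 20 models + internal predictions.

    ``model_factory(test_fold, val_fold)`` returns a fresh unfitted model.
    ``preprocess(X, train_indices)`` may return ``(X_transformed, apply_fn)``
    to fit per-partition transforms (e.g. standardization) without leakage.
    Returns ``(models, internal_prediction_set, assignments)`` where
    ``assignments`` records the (test, validation) fold pair of each model.
    """
    y = np.asarray(y).astype(int)
    k = fold_plan.k
    n = len(y)
    internal = np.full(n, np.nan)
    models, assignments = [], []
    for test_fold in range(k):
        test_idx = fold_plan.fold_members(test_fold)
        fold_probs = []
        for val_fold in range(k):
            if val_fold == test_fold:
                continue
            train_idx = np.flatnonzero(~np.isin(fold_plan.fold_index,
                                                [test_fold, val_fold]))
            if preprocess is not None:
                X_t, apply_fn = preprocess(X, train_idx)
            else:
                X_t, apply_fn = X, None
            model = model_factory(test_fold, val_fold)
            try:
                model.fit(_take(X_t, train_idx), y[train_idx])
            except Exception as exc:
                raise RuntimeError(
                    f"model training failed for (test={test_fold}, "
                    f"val={val_fold}): {exc}") from exc
            models.append(model if apply_fn is None else _WrappedModel(model, apply_fn))
            assignments.append((test_fold, val_fold))
            fold_probs.append(models[-1].predict_proba(_take(X, test_idx)))
        internal[test_idx] = np.mean(fold_probs, axis=0)
    assert not np.isnan(internal).any(), "every patient must be predicted once"
    pred = PredictionSet([fold_plan.patient_ids[i] for i in range(n)], internal)
    return models, pred, assignments


class _WrappedModel:
    """Bundles a fitted model with its per-partition preprocessing."""

    def __init__(self, model, apply_fn):
        self.model = model
        self.apply_fn = apply_fn

    def predict_proba(self, X):
        return self.model.predict_proba(self.apply_fn(X))

    def predict(self, X):
        return (self.predict_proba(X) >= PROBABILITY_THRESHOLD).astype(int)


def _take(X, idx):
    if isinstance(X, pd.DataFrame):
        return X.iloc[idx]
    return np.asarray(X)[idx]


def external_predict(models, X, patient_ids=None) -> PredictionSet:
    """Mean class-1 probability of all (20) models per external patient."""
    if not models:
        raise ValueError("no fitted models supplied")
    probs = np.mean([m.predict_proba(X) for m in models], axis=0)
    if patient_ids is None:
        patient_ids = list(range(len(probs)))
    return PredictionSet(list(patient_ids), probs)


def ensemble_combine(*prediction_sets: PredictionSet) -> PredictionSet:
    """Element-wise mean probability across model families."""
    if not prediction_sets:
        raise ValueError("nothing to combine")
    ids = prediction_sets[0].patient_ids
    for ps in prediction_sets[1:]:
        if list(ps.patient_ids) != list(ids):
            raise ValueError("patient ids do not match across prediction sets")
    mean = np.mean([ps.probabilities for ps in prediction_sets], axis=0)
    return PredictionSet(list(ids), mean)


def _safe_div(num: float, den: float, flags: list, name: str) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def metric_suite(y_true, y_prob, threshold: float = PROBABILITY_THRESHOLD
                 ) -> tuple[dict[str, float], list[str]]:
    """All eight metrics from probabilities; degenerate denominators give 0.

    Returns ``(metrics, flags)`` where flags names any metric that hit a
    degenerate denominator. ``mcc_scaled`` is (MCC + 1) / 2; ``f1_class0``
    treats class 0 as the positive class; AUC is the rank statistic (0
    flagged when only one class is present).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    y = np.asarray(y_true).astype(int)
    p = np.asarray(y_prob, dtype=np.float64)
    pred = (p >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    flags: list[str] = []

    accuracy = (tp + tn) / len(y)
    precision = _safe_div(tp, tp + fp, flags, "precision")
    recall = _safe_div(tp, tp + fn, flags, "recall")
    specificity = _safe_div(tn, tn + fp, flags, "specificity")
    f1_c1 = _safe_div(2 * tp, 2 * tp + fp + fn, flags, "f1_class1")
    f1_c0 = _safe_div(2 * tn, 2 * tn + fn + fp, flags, "f1_class0")
    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if mcc_den == 0:
        flags.append("mcc_scaled")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / mcc_den
    if len(np.unique(y)) < 2:
        flags.append("auc")
        auc = 0.0
    else:
        auc = float(roc_auc_score(y, p))
    metrics = {
        "accuracy": accuracy, "auc": auc, "mcc_scaled": (mcc + 1.0) / 2.0,
        "f1_class1": f1_c1, "f1_class0": f1_c0,
        "precision": precision, "recall": recall, "specificity": specificity,
    }
    return metrics, flags


@dataclass
class MetricReport:
    median: dict[str, float]
    lower: dict[str, float]             # 2.5 percentile
    upper: dict[str, float]             # 97.5 percentile
    n_bootstrap: int
    ratio: str = "1:1"
    flags: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"median": self.median, "p2.5": self.lower,
                             "p97.5": self.upper})


def balanced_bootstrap_metrics(y_true, y_prob, n_boot: int = 1000,
                               seed: int = 0,
                               threshold: float = PROBABILITY_THRESHOLD
                               ) -> MetricReport:
    """Metrics over bootstrap replicates with a 1:1 class ratio.

    Each replicate draws ``min(class counts)`` patients with replacement
    from each class, so replicates are exactly balanced; medians and the
    2.5/97.5 percentile interval are reported.
    """
    y = np.asarray(y_true).astype(int)
    p = np.asarray(y_prob, dtype=np.float64)
    idx0 = np.flatnonzero(y == 0)
    idx1 = np.flatnonzero(y == 1)
    if len(idx0) == 0 or len(idx1) == 0:
        raise ValueError("both classes must be present")
    m = min(len(idx0), len(idx1))
    rng = np.random.default_rng(seed)
    samples = {name: np.empty(n_boot) for name in METRIC_NAMES}
    flag_counts: dict[str, int] = {}
    for b in range(n_boot):
        take0 = rng.choice(idx0, size=m, replace=True)
        take1 = rng.choice(idx1, size=m, replace=True)
        take = np.concatenate([take0, take1])
        metrics, flags = metric_suite(y[take], p[take], threshold)
        for name in METRIC_NAMES:
            samples[name][b] = metrics[name]
        for f in flags:
            flag_counts[f] = flag_counts.get(f, 0) + 1
    return MetricReport(
        median={k: float(np.median(v)) for k, v in samples.items()},
        lower={k: float(np.percentile(v, 2.5)) for k, v in samples.items()},
        upper={k: float(np.percentile(v, 97.5)) for k, v in samples.items()},
        n_bootstrap=n_boot, flags=flag_counts)
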