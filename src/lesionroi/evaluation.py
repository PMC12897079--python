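"""Evaluation: patient-level partitioning, metrics, ROC/AUC with DeLong's
test, soft-voting aggregation, cross-validation, and cohort statistics.

Conventions: AME is the positive class (label 1), OKC negative (label 0).
AUC is the Mann-Whitney pair statistic (ties count one half); its variance
and the covariance between two correlated ROC curves come from DeLong's
structural-components (midrank) method, so paired AUCs can be compared
with a normal z-test. Specificity is TN / (TN + FP), the quantity whose
complement is the ROC x-axis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError, ConfigurationError, DegenerateInputError

__all__ = [
    "FoldPartition",
    "ConfusionMatrix",
    "MetricsReport",
    "RocResult",
    "ContingencyTable",
    "partition_patients",
    "confusion_from_predictions",
    "classification_metrics",
    "patient_soft_vote",
    "roc_auc",
    "delong_test",
    "pearson_chi_square",
    "mann_whitney_u",
    "cross_validate",
    "aggregate_fold_metrics",
]


# --------------------------------------------------------------------- folds
@dataclass(frozen=True)
class FoldPartition:
    """Patient-level fold assignment (no patient in two folds)."""

    k: int
    assignment: Mapping[str, int]
    stratified: bool

    def fold_patients(self, fold: int) -> list[str]:
        return [p for p, f in self.assignment.items() if f == fold]


def partition_patients(
    patient_ids: Sequence[str],
    labels: Sequence[int],
    k: int = 5,
    seed: int = 0,
    stratify: bool = True,
) -> FoldPartition:
    """Assign patients to k folds, optionally stratified by label.

    Within each stratum the fold sizes differ by at most one; the whole
    assignment is deterministic in ``seed``.
    """
    patient_ids = [str(p) for p in patient_ids]
    labels = list(labels)
    if len(patient_ids) != len(labels):
        raise AlignmentError("patient_ids and labels differ in length")
    if len(set(patient_ids)) != len(patient_ids):
        raise ConfigurationError("duplicate patient ids")
    if k < 2 or k > len(patient_ids):
        raise ConfigurationError(f"k={k} incompatible with {len(patient_ids)} patients")
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    strata = sorted(set(labels)) if stratify else [None]
    offset = 0
    for stratum in strata:
        members = [p for p, l in zip(patient_ids, labels) if stratify is False or l == stratum]
        members = sorted(members)
        rng.shuffle(members)
        for i, pid in enumerate(members):
            assignment[pid] = (i + offset) % k
        offset += len(members)  # rotate so strata remainders spread across folds
    return FoldPartition(k=k, assignment=assignment, stratified=stratify)


# ------------------------------------------------------------------- metrics
@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_from_predictions(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise AlignmentError("y_true and y_pred differ in length")
    return ConfusionMatrix(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    level: str = "slice"

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "specificity": self.specificity,
            "f1": self.f1,
        }


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN", RuntimeWarning)
        return float("nan")
    return num / den


def classification_metrics(cm: ConfusionMatrix, level: str = "slice") -> MetricsReport:
    """Accuracy, precision, recall, specificity, F1 from a confusion matrix.

    Undefined ratios (zero denominators) are reported as NaN with a
    warning, never silently as 0.
    """
    if cm.total == 0:
        raise DegenerateInputError("empty confusion matrix")
    precision = _ratio(cm.tp, cm.tp + cm.fp, "precision")
    recall = _ratio(cm.tp, cm.tp + cm.fn, "recall")
    specificity = _ratio(cm.tn, cm.tn + cm.fp, "specificity")
    if math.isnan(precision) or math.isnan(recall) or (precision + recall) == 0:
        f1 = float("nan")
        if not (math.isnan(precision) or math.isnan(recall)):
            warnings.warn("f1 undefined (precision + recall = 0); reporting NaN", RuntimeWarning)
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricsReport(
        accuracy=(cm.tp + cm.tn) / cm.total,
        precision=precision,
        recall=recall,
        specificity=specificity,
        f1=f1,
        level=level,
    )


def patient_soft_vote(slice_probs: Sequence[float], threshold: float = 0.5) -> tuple[float, int]:
    """Soft voting: patient probability = mean of slice probabilities.

    Predicted class is 1 (AME) iff the mean is >= ``threshold``.
    """
    probs = np.asarray(slice_probs, dtype=float)
    if probs.size == 0:
        raise DegenerateInputError("no slice probabilities for patient")
    mean = float(probs.mean())
    return mean, int(mean >= threshold)


# ----------------------------------------------------------------- ROC / AUC
@dataclass(frozen=True)
class RocResult:
    auc: float
    delong_variance: float
    n_pos: int
    n_neg: int


def _delong_components(labels: np.ndarray, scores: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and DeLong structural components (V10 per positive, V01 per negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise DegenerateInputError("ROC needs both classes present")
    all_scores = np.concatenate([pos, neg])
    tz = stats.rankdata(all_scores)  # midranks
    tx = stats.rankdata(pos)
    ty = stats.rankdata(neg)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    auc = float(v10.mean())
    return auc, v10, v01


def roc_auc(labels: Sequence[int], scores: Sequence[float]) -> RocResult:
    """Mann-Whitney AUC with the DeLong variance of the estimator."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise AlignmentError("labels and scores differ in length")
    auc, v10, v01 = _delong_components(labels, scores)
    m, n = len(v10), len(v01)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return RocResult(auc=auc, delong_variance=s10 / m + s01 / n, n_pos=m, n_neg=n)


def delong_test(
    labels: Sequence[int],
    scores_a: Sequence[float],
    scores_b: Sequence[float],
) -> tuple[float, float, float, float]:
    """DeLong's test for two correlated AUCs on the same cases.

    Returns ``(auc_a, auc_b, z, p)`` with a two-sided p from the normal
    approximation of AUC_A - AUC_B with the paired DeLong covariance.
    """
    labels = np.asarray(labels, dtype=int)
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if not (labels.shape == scores_a.shape == scores_b.shape):
        raise AlignmentError("labels, scores_a and scores_b must be aligned")
    auc_a, v10_a, v01_a = _delong_components(labels, scores_a)
    auc_b, v10_b, v01_b = _delong_components(labels, scores_b)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    delta = auc_a - auc_b
    if var_diff <= 0:
        if abs(delta) < 1e-12:
            return auc_a, auc_b, 0.0, 1.0
        warnings.warn(
            "DeLong variance of the AUC difference is zero with unequal AUCs; "
            "result is numerically degenerate",
            RuntimeWarning,
        )
        return auc_a, auc_b, float("nan"), float("nan")
    z = delta / math.sqrt(var_diff)
    p = 2.0 * stats.norm.sf(abs(z))
    return auc_a, auc_b, float(z), float(p)


# ------------------------------------------------------- cohort statistics
@dataclass(frozen=True)
class ContingencyTable:
    """Category-by-group counts (columns: AME, OKC)."""

    counts: tuple[tuple[int, ...], ...]
    row_labels: tuple[str, ...] = ()
    name: str = ""

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)


def pearson_chi_square(table: ContingencyTable | Sequence[Sequence[int]]) -> tuple[float, int, float]:
    """Pearson chi-square without continuity correction: (statistic, df, p)."""
    arr = table.as_array() if isinstance(table, ContingencyTable) else np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ConfigurationError("contingency table must be at least 2x2")
    if np.any(arr < 0):
        raise ConfigurationError("negative cell count")
    expected = stats.contingency.expected_freq(arr)
    if np.any(expected <= 0):
        raise ConfigurationError("zero expected count in contingency table")
    statistic, p, df, _ = stats.chi2_contingency(arr, correction=False)
    return float(statistic), int(df), float(p)


def mann_whitney_u(sample_x: Sequence[float], sample_y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact distribution for small samples (both n < 20, no ties), normal
    approximation with tie correction otherwise.
    """
    x = np.asarray(sample_x, dtype=float)
    y = np.asarray(sample_y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ConfigurationError("both samples must be nonempty")
    small = min(x.size, y.size) < 20 and max(x.size, y.size) < 20
    method = "exact" if small and len(np.unique(np.concatenate([x, y]))) == x.size + y.size else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


# ------------------------------------------------------------ cross-validate
@dataclass
class FoldResult:
    fold: int
    slice_metrics: MetricsReport
    patient_metrics: MetricsReport
    slice_roc: RocResult
    patient_roc: RocResult
    predictions: pd.DataFrame  # patient_id, slice_index, label, prob, fold


@dataclass
class CrossValResult:
    variant: str
    folds: list[FoldResult] = field(default_factory=list)

    @property
    def predictions(self) -> pd.DataFrame:
        return pd.concat([f.predictions for f in self.folds], ignore_index=True)

    def patient_predictions(self) -> pd.DataFrame:
        rows = []
        for f in self.folds:
            for pid, grp in f.predictions.groupby("patient_id", sort=True):
                mean, pred = patient_soft_vote(grp["prob"].to_numpy())
                rows.append(
                    {
                        "patient_id": pid,
                        "fold": f.fold,
                        "label": int(grp["label"].iloc[0]),
                        "prob": mean,
                        "pred": pred,
                    }
                )
        return pd.DataFrame(rows).sort_values("patient_id", ignore_index=True)


def aggregate_fold_metrics(result: CrossValResult) -> pd.DataFrame:
    """Fold mean +/- sample SD of every metric, at both levels."""
    rows = []
    for level in ("slice", "patient"):
        per_fold = pd.DataFrame(
            [
                {
                    **(f.slice_metrics if level == "slice" else f.patient_metrics).as_dict(),
                    "auc": (f.slice_roc if level == "slice" else f.patient_roc).auc,
                }
                for f in result.folds
            ]
        )
        for metric in per_fold.columns:
            vals = per_fold[metric].to_numpy(dtype=float)
            finite = vals[np.isfinite(vals)]
            rows.append(
                {
                    "variant": result.variant,
                    "level": level,
                    "metric": metric,
                    "mean": float(finite.mean()) if finite.size else float("nan"),
                    "sd": float(finite.std(ddof=1)) if finite.size > 1 else 0.0,
                }
            )
    return pd.DataFrame(rows)


def cross_validate(
    samples,
    partition: FoldPartition,
    backend_factory,
    variant: str = "",
    seed: int = 0,
    eval_seed: int = 0,
) -> CrossValResult:
    """Patient-level k-fold cross-validation of one ROI variant.

    ``samples`` is a list of SliceSamples (one variant); for each fold the
    backend trains on the other folds (MAPS-weighted draws, early stopping
    monitored on the held-out fold) and is evaluated on the held-out fold
    with uniform patient batches. Slice- and patient-level metrics and ROC
    results are produced per fold.
    """
    from .backend import predict_slices, train
    from .sampling import uniform_patient_batches

    result = CrossValResult(variant=variant)
    by_patient: dict[str, list] = {}
    for s in samples:
        by_patient.setdefault(s.patient_id, []).append(s)
    for pid in by_patient:
        by_patient[pid].sort(key=lambda s: s.slice_index)
    missing = set(by_patient) - set(partition.assignment)
    if missing:
        raise ConfigurationError(f"samples contain patients outside the partition: {sorted(missing)[:5]}")

    for fold in range(partition.k):
        test_pids = [p for p in by_patient if partition.assignment[p] == fold]
        train_samples = [s for p in by_patient if partition.assignment[p] != fold for s in by_patient[p]]
        test_counts = {p: len(by_patient[p]) for p in test_pids}
        plan = uniform_patient_batches(test_counts, seed=eval_seed + fold)
        eval_samples = [by_patient[pid][i] for pid, i in plan]

        backend = backend_factory()
        backend, _ = train(backend, train_samples, eval_samples, seed=seed + fold)
        probs = predict_slices(backend, eval_samples)

        pred_df = pd.DataFrame(
            {
                "patient_id": [s.patient_id for s in eval_samples],
                "slice_index": [s.slice_index for s in eval_samples],
                "label": [s.label for s in eval_samples],
                "prob": probs,
                "fold": fold,
            }
        )
        slice_cm = confusion_from_predictions(pred_df["label"], (pred_df["prob"] >= 0.5).astype(int))
        pat_rows = []
        for pid, grp in pred_df.groupby("patient_id", sort=True):
            mean, pred = patient_soft_vote(grp["prob"].to_numpy())
            pat_rows.append({"label": int(grp["label"].iloc[0]), "prob": mean, "pred": pred})
        pat_df = pd.DataFrame(pat_rows)
        pat_cm = confusion_from_predictions(pat_df["label"], pat_df["pred"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            slice_metrics = classification_metrics(slice_cm, level="slice")
            patient_metrics = classification_metrics(pat_cm, level="patient")
        result.folds.append(
            FoldResult(
                fold=fold,
                slice_metrics=slice_metrics,
                patient_metrics=patient_metrics,
                slice_roc=roc_auc(pred_df["label"], pred_df["prob"]),
                patient_roc=roc_auc(pat_df["label"], pat_df["prob"]),
                predictions=pred_df,
            )
        )
    return result
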