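"""Calibration and evaluation metrics for disorder prediction.

Residue-level metrics (AUC, AUPRC, MCC, F1, sensitivity) are computed on
the pooled residues of a dataset (micro-average).  Binary calls are
produced from real-valued propensities with a single dataset-wide
threshold chosen so that the number of predicted disordered residues over
the whole benchmark matches the native count — this calibrates binary
predictions across methods with very different score scales.

Protein-level evaluation covers disorder content (MAE and Spearman
correlation between predicted and native per-protein content) and the
identification of fully disordered proteins (F1 and sensitivity at
content cut-offs 0.99 / 0.90 / 0.80).

Thresholding and cut-off comparisons use strict ``>`` throughout:
residues with propensities *above* the cut-off are predicted disordered,
and a protein is fully disordered when its content *exceeds* the cut-off.
"""

from __future__ import annotations

import logging
import math
from typing import Dict, Iterable, Mapping, Sequence, Tuple

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .errors import ParameterError, UndefinedMetricError
from .types import (
    BinaryMetrics,
    CalibratedThreshold,
    ConfusionCounts,
    ReferenceEntry,
    ScoreProfile,
)

logger = logging.getLogger(__name__)

#: Content cut-offs defining fully disordered proteins.
FDP_CUTOFFS = (0.99, 0.90, 0.80)


def calibrate_threshold(profiles: Iterable[ScoreProfile],
                        references: Mapping[str, ReferenceEntry],
                        method: str = "") -> CalibratedThreshold:
    """Choose the dataset-wide cut-off matching the native disorder count.

    The threshold is the smallest candidate in ``{observed scores} ∪ {0}``
    minimizing ``|#{scores > t} - native_count|`` over the pooled residues
    of all profiles with a matching reference; ties in the objective are
    broken toward fewer predicted disordered residues (larger t).
    """
    pooled_scores = []
    native_count = 0
    for profile in profiles:
        ref = references.get(profile.id)
        if ref is None:
            raise ParameterError(f"profile {profile.id} has no matching reference")
        if len(profile) != ref.length:
            raise ParameterError(
                f"{profile.id}: profile length {len(profile)} != reference {ref.length}"
            )
        pooled_scores.append(profile.scores)
        native_count += int(ref.disorder.sum())
        if not method:
            method = profile.method
    if not pooled_scores:
        raise ParameterError("empty profile pool")
    scores = np.sort(np.concatenate(pooled_scores))
    if scores.size == 0:
        raise ParameterError("empty residue pool")
    candidates = np.unique(np.concatenate([[0.0], scores]))
    # strictly-above counts via binary search on the sorted pool
    above = scores.size - np.searchsorted(scores, candidates, side="right")
    objective = np.abs(above - native_count)
    best = objective.min()
    mask = objective == best
    # among minimizers prefer fewer predicted (larger t); then smallest t.
    min_above = above[mask].min()
    idx = np.nonzero(mask & (above == min_above))[0][0]
    return CalibratedThreshold(
        method=method,
        threshold=float(candidates[idx]),
        target_count=native_count,
        achieved_count=int(above[idx]),
    )


def binarize(profile: ScoreProfile, threshold) -> ScoreProfile:
    """Fill binary calls: 1 iff score strictly above the threshold."""
    t = threshold.threshold if isinstance(threshold, CalibratedThreshold) else float(threshold)
    return ScoreProfile(
        id=profile.id,
        method=profile.method,
        scores=profile.scores,
        binary=(profile.scores > t).astype(np.int8),
        residues=profile.residues,
    )


def _check_binary_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.size and not np.isin(labels, (0, 1)).all():
        raise ParameterError("labels must be over {0,1}")
    return labels


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """ROC AUC: the Mann-Whitney probability with ties counted 1/2.

    Invariant under strictly increasing score transforms.  Raises
    :class:`UndefinedMetricError` on single-class labels.
    """
    labels = _check_binary_labels(labels)
    scores = np.asarray(scores, dtype=np.float64)
    if labels.size == 0 or labels.min() == labels.max():
        raise UndefinedMetricError("ROC AUC undefined without both classes")
    return float(roc_auc_score(labels, scores))


def pr_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Precision-recall AUC in the average-precision formulation."""
    labels = _check_binary_labels(labels)
    scores = np.asarray(scores, dtype=np.float64)
    if labels.size == 0 or labels.sum() == 0:
        raise UndefinedMetricError("AUPRC undefined without positives")
    return float(average_precision_score(labels, scores))


def confusion(binary: Sequence[int], labels: Sequence[int]) -> ConfusionCounts:
    """Confusion counts with disorder (1) as the positive class."""
    binary = _check_binary_labels(binary)
    labels = _check_binary_labels(labels)
    if binary.shape != labels.shape:
        raise ParameterError("binary/labels length mismatch")
    tp = int(np.sum((binary == 1) & (labels == 1)))
    tn = int(np.sum((binary == 0) & (labels == 0)))
    fp = int(np.sum((binary == 1) & (labels == 0)))
    fn = int(np.sum((binary == 0) & (labels == 1)))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def binary_metrics(c: ConfusionCounts) -> BinaryMetrics:
    """MCC, F1 and sensitivity from confusion counts.

    Zero denominators yield metric 0 with ``degenerate=True`` instead of
    an error, so dataset aggregation never aborts.
    """
    degenerate = False
    f1_denom = 2 * c.tp + c.fp + c.fn
    if f1_denom:
        f1 = 2 * c.tp / f1_denom
    else:
        f1, degenerate = 0.0, True
    if c.tp + c.fn:
        sensitivity = c.tp / (c.tp + c.fn)
    else:
        sensitivity, degenerate = 0.0, True
    mcc_denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if mcc_denom:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(mcc_denom)
    else:
        mcc, degenerate = 0.0, True
    return BinaryMetrics(mcc=mcc, f1=f1, sensitivity=sensitivity, degenerate=degenerate)


def disorder_content(series: Sequence[int]) -> float:
    """Fraction of 1s in a per-residue label or binary-call series."""
    series = _check_binary_labels(series)
    if series.size == 0:
        raise ParameterError("empty series")
    return float(series.mean())


def content_mae(pred: Sequence[float], native: Sequence[float]) -> float:
    """Mean absolute error between per-protein content vectors."""
    pred = np.asarray(pred, dtype=np.float64)
    native = np.asarray(native, dtype=np.float64)
    if pred.shape != native.shape or pred.size == 0:
        raise ParameterError("content vectors must have equal nonzero length")
    return float(np.mean(np.abs(pred - native)))


def content_scc(pred: Sequence[float], native: Sequence[float]) -> float:
    """Spearman correlation of predicted vs native content (average ranks
    for ties; equals the classic 1 - 6*sum(d^2)/(n(n^2-1)) with no ties)."""
    pred = np.asarray(pred, dtype=np.float64)
    native = np.asarray(native, dtype=np.float64)
    if pred.shape != native.shape or pred.size < 2:
        raise ParameterError("content vectors must have equal length >= 2")
    if np.ptp(pred) == 0 or np.ptp(native) == 0:
        raise UndefinedMetricError("Spearman undefined with zero variance")
    rho = stats.spearmanr(pred, native).statistic
    return float(rho)


def fdp_eval(pred_content: Sequence[float], native_content: Sequence[float],
             cutoff: float) -> Tuple[float, float]:
    """Protein-level fully-disordered evaluation at a content cut-off.

    A protein is native-FDP iff its native content strictly exceeds the
    cut-off, and predicted-FDP iff its predicted content does; returns
    (F1, sensitivity) of the resulting protein-level classification.
    """
    pred = np.asarray(pred_content, dtype=np.float64)
    native = np.asarray(native_content, dtype=np.float64)
    if pred.shape != native.shape:
        raise ParameterError("content vectors must have equal length")
    native_fdp = native > cutoff
    pred_fdp = pred > cutoff
    if not native_fdp.any():
        raise UndefinedMetricError(f"no native fully disordered proteins at {cutoff}")
    c = confusion(pred_fdp.astype(int), native_fdp.astype(int))
    m = binary_metrics(c)
    return m.f1, m.sensitivity


def per_protein_auc(profiles: Mapping[str, ScoreProfile],
                    references: Mapping[str, ReferenceEntry]) -> Dict[str, float]:
    """Per-protein ROC AUC; proteins with single-class labels are skipped."""
    out: Dict[str, float] = {}
    for pid, profile in profiles.items():
        ref = references.get(pid)
        if ref is None:
            continue
        try:
            out[pid] = roc_auc(profile.scores, ref.disorder)
        except UndefinedMetricError:
            continue
    return out


def pooled_residue_eval(profiles: Mapping[str, ScoreProfile],
                        references: Mapping[str, ReferenceEntry],
                        threshold: CalibratedThreshold,
                        ids: Iterable[str] | None = None) -> dict:
    """AUC/AUPRC/MCC/F1/sensitivity on the pooled residues of ``ids``.

    Proteins without a profile are skipped (partial coverage is reported,
    not fatal).
    """
    if ids is None:
        ids = list(profiles)
    scores, labels = [], []
    covered = 0
    total = 0
    for pid in ids:
        ref = references.get(pid)
        if ref is None:
            continue
        total += 1
        profile = profiles.get(pid)
        if profile is None:
            continue
        covered += 1
        scores.append(profile.scores)
        labels.append(ref.disorder)
    if not scores:
        raise UndefinedMetricError("no covered proteins in pool")
    pooled_scores = np.concatenate(scores)
    pooled_labels = np.concatenate(labels)
    binary = (pooled_scores > threshold.threshold).astype(np.int8)
    m = binary_metrics(confusion(binary, pooled_labels))
    return {
        "auc": roc_auc(pooled_scores, pooled_labels),
        "auprc": pr_auc(pooled_scores, pooled_labels),
        "mcc": m.mcc,
        "f1": m.f1,
        "sensitivity": m.sensitivity,
        "coverage": covered / total if total else 0.0,
    }
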