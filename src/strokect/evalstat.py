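"""Score aggregation and statistical evaluation.

Patch probabilities are averaged per lesion (bag-of-local-features) and
the subject score is the maximum over its lesions. Evaluation covers ROC
and AUC, bootstrap confidence intervals, confounder-stratified test-set
construction (scanner model, age decade) and confusion matrices at a
fixed operating threshold.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import DataError, ParameterError, StratificationError

__all__ = [
    "SubjectRecord", "SubjectScore", "EvalResult", "lesion_score",
    "subject_score", "roc_auc", "bootstrap_auc_ci", "stratify_test_set",
    "confusion_at_threshold", "save_predictions_csv",
]


@dataclass
class SubjectRecord:
    subject_id: str
    age: float
    scanner_model: str
    label: int  # 1 = stroke, 0 = healthy
    split: str = ""

    def __post_init__(self):
        if self.age < 0:
            raise ParameterError(f"age must be >= 0, got {self.age}")
        if self.label not in (0, 1):
            raise ParameterError(f"label must be 0 or 1, got {self.label}")

    @property
    def age_decade(self) -> int:
        return int(self.age // 10)


@dataclass
class SubjectScore:
    subject_id: str
    lesion_scores: list[float] = field(default_factory=list)

    @property
    def score(self) -> float:
        return subject_score(self.lesion_scores)


@dataclass
class EvalResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    ci: tuple[float, float] | None = None
    confusion: dict[str, int] | None = None
    stratify_key: str | None = None


def lesion_score(patch_probabilities) -> float:
    """Mean of the patch probabilities on one lesion."""
    probs = np.asarray(list(patch_probabilities), dtype=float)
    if probs.size == 0:
        raise ParameterError("lesion_score requires at least one patch probability")
    return float(probs.mean())


def subject_score(lesion_scores) -> float:
    """Maximum lesion score; 0.0 when no lesion was proposed."""
    scores = list(lesion_scores)
    if not scores:
        return 0.0
    return float(max(scores))


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise DataError("both classes must be present")


def roc_auc(scores, labels) -> EvalResult:
    """ROC curve and AUC (probability a positive outscores a negative,
    ties counting one half)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    fpr, tpr, _ = _sk_roc_curve(labels, scores)
    return EvalResult(fpr=fpr, tpr=tpr, auc=float(_sk_auc(fpr, tpr)))


def bootstrap_auc_ci(scores, labels, reps: int = 1000, m: int = 100,
                     seed: int = 0, max_retries: int = 1000) -> tuple[float, float]:
    """95% bootstrap CI for the AUC.

    ``reps`` resamples of size ``m`` are drawn with replacement; the CI is
    the (min, max) of the central 95% of the sorted resample AUCs
    (nearest-rank percentiles). Single-class resamples are redrawn.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    if reps <= 0 or m <= 0:
        raise ParameterError("reps and m must be positive")
    rng = np.random.default_rng(seed)
    n = len(scores)
    aucs = np.empty(reps)
    for r in range(reps):
        for _ in range(max_retries):
            idx = rng.integers(0, n, size=m)
            if len(np.unique(labels[idx])) == 2:
                break
        else:
            raise DataError("could not draw a two-class bootstrap resample")
        aucs[r] = roc_auc(scores[idx], labels[idx]).auc
    aucs.sort()
    lo_idx = int(np.floor(0.025 * reps))
    hi_idx = int(np.ceil(0.975 * reps)) - 1
    return float(aucs[lo_idx]), float(aucs[hi_idx])


def stratify_test_set(records, key: str = "scanner", seed: int = 0):
    """Balanced subset: within every stratum, sample min(n_stroke,
    n_healthy) subjects of each class without replacement. Strata missing
    a class contribute nothing."""
    if key not in ("scanner", "age_decade"):
        raise ParameterError(f"unknown stratification key {key!r}")
    rng = np.random.default_rng(seed)
    strata: dict[object, list[SubjectRecord]] = {}
    for rec in records:
        k = rec.scanner_model if key == "scanner" else rec.age_decade
        strata.setdefault(k, []).append(rec)
    selected: list[SubjectRecord] = []
    for k in sorted(strata, key=str):
        group = strata[k]
        stroke = [r for r in group if r.label == 1]
        healthy = [r for r in group if r.label == 0]
        take = min(len(stroke), len(healthy))
        if take == 0:
            continue
        sel_s = rng.choice(len(stroke), size=take, replace=False)
        sel_h = rng.choice(len(healthy), size=take, replace=False)
        selected.extend(stroke[i] for i in sel_s)
        selected.extend(healthy[i] for i in sel_h)
    if not selected:
        raise StratificationError("every stratum lacks one of the classes")
    return selected


def confusion_at_threshold(scores, labels, t: float = 0.3) -> dict[str, int]:
    """2x2 confusion counts; predicted positive iff score >= t."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = scores >= t
    pos = labels == 1
    return {
        "TP": int(np.sum(pred & pos)),
        "FP": int(np.sum(pred & ~pos)),
        "FN": int(np.sum(~pred & pos)),
        "TN": int(np.sum(~pred & ~pos)),
    }


def save_predictions_csv(subject_ids, scores, labels, path) -> None:
    """Write per-subject predictions (subject_id, score, label)."""
    pd.DataFrame({"subject_id": list(subject_ids),
                  "score": list(scores),
                  "label": list(labels)}).to_csv(path, index=False)


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame([
        {"subject_id": r.subject_id, "age": r.age, "scanner_model": r.scanner_model,
         "label": r.label, "split": r.split} for r in records])
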