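"""AHI estimation, severity grading, decision-boundary calibration and
agreement statistics.

The estimated AHI divides positively-classified episodes by total recording
time (a respiratory event index), whereas the reference AHI uses sleep time
when annotated — so systematic underestimation is expected and the severity
boundaries separating normal/mild/moderate/severe are recalibrated by grid
search on training subjects (maximising 4-class accuracy, ties broken by
kappa then by proximity to the clinical 5/15/30 thresholds), then aggregated
over cross-validation folds by component-wise median.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .types import (ApneaAnnotation, NOMINAL_BOUNDARIES,
                    SEVERITY_CLASSES, SeverityBoundaries, SubjectAssessment,
                    ValidationError, severity_from_ahi)

_CLASS_INDEX = {c: i for i, c in enumerate(SEVERITY_CLASSES)}


def estimate_ahi(positive_episodes, duration_h: float) -> float:
    """Positively-classified episodes per hour of total recording time.

    ``positive_episodes`` may be a count or a sequence of episodes (only
    those with ``prediction == 1`` are counted).
    """
    if not duration_h > 0:
        raise ValidationError("duration_h must be > 0")
    if isinstance(positive_episodes, (int, np.integer)):
        n = int(positive_episodes)
    else:
        n = sum(1 for e in positive_episodes if e.prediction == 1)
    if n < 0:
        raise ValidationError("negative event count")
    return n / duration_h


def classify_severity(ahi: float,
                      boundaries: SeverityBoundaries = NOMINAL_BOUNDARIES
                      ) -> str:
    """Ordinal severity class of an AHI; lower band edges inclusive."""
    return severity_from_ahi(ahi, boundaries)


# ---------------------------------------------------------------------------
# confusion / kappa helpers

def confusion_matrix(true_idx: np.ndarray, pred_idx: np.ndarray,
                     n_classes: int) -> np.ndarray:
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (true_idx, pred_idx), 1)
    return cm


def accuracy_kappa(cm: np.ndarray) -> Tuple[float, float]:
    """Overall accuracy and unweighted Cohen's kappa of a confusion matrix
    (rows = true class, columns = predicted class)."""
    cm = np.asarray(cm, dtype=float)
    total = cm.sum()
    if total == 0:
        raise ValidationError("empty confusion matrix")
    po = np.trace(cm) / total
    pe = (cm.sum(axis=1) * cm.sum(axis=0)).sum() / total ** 2
    kappa = 0.0 if pe == 1.0 else (po - pe) / (1.0 - pe)
    return float(po), float(kappa)


def collapse_two_class(true_idx: np.ndarray, pred_idx: np.ndarray,
                       threshold_class: int = 2):
    """Collapse 4-class labels to normal+mild (0) vs moderate+severe (1)."""
    return (true_idx >= threshold_class).astype(int), \
        (pred_idx >= threshold_class).astype(int)


# ---------------------------------------------------------------------------
# boundary calibration

def default_boundary_grid(b1_spec=(0.5, 10.0, 0.5), b2_spec=(0.5, 20.0, 0.5),
                          b3_spec=(1.0, 40.0, 1.0)) -> np.ndarray:
    """All ordered triples (b1, b2, b3): b1 over its range, b2 from
    b1 + offset to its cap, b3 from b2 + offset to its cap."""
    triples = []
    b1_lo, b1_hi, b1_step = b1_spec
    b2_off, b2_hi, b2_step = b2_spec
    b3_off, b3_hi, b3_step = b3_spec
    for b1 in np.arange(b1_lo, b1_hi + 1e-9, b1_step):
        for b2 in np.arange(b1 + b2_off, b2_hi + 1e-9, b2_step):
            for b3 in np.arange(b2 + b3_off, b3_hi + 1e-9, b3_step):
                triples.append((b1, b2, b3))
    return np.array(triples)


def adjust_boundaries(pairs: Sequence[Tuple[float, str]],
                      grid: Optional[np.ndarray] = None
                      ) -> SeverityBoundaries:
    """Grid-search the severity boundaries that best map estimated AHIs to
    the true classes of the training subjects.

    Maximises 4-class accuracy; ties broken by higher kappa, then by
    smallest L1 distance to the nominal (5, 15, 30), then lexicographically.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValidationError("no training pairs")
    classes = {c for _, c in pairs}
    missing = set(SEVERITY_CLASSES) - classes
    if missing:
        raise ValidationError(
            f"boundary adjustment needs >= 1 subject per class; missing "
            f"{sorted(missing)}")
    grid = default_boundary_grid() if grid is None else np.asarray(grid)
    if grid.size == 0:
        raise ValidationError("empty boundary grid")
    ahi = np.array([a for a, _ in pairs])
    true_idx = np.array([_CLASS_INDEX[c] for _, c in pairs])
    pred = ((ahi[None, :] >= grid[:, 0:1]).astype(int)
            + (ahi[None, :] >= grid[:, 1:2])
            + (ahi[None, :] >= grid[:, 2:3]))
    acc = (pred == true_idx[None, :]).mean(axis=1)
    best_acc = acc.max()
    tie = np.flatnonzero(acc >= best_acc - 1e-12)
    if len(tie) > 1:
        kappas = np.array([
            accuracy_kappa(confusion_matrix(true_idx, pred[k], 4))[1]
            for k in tie])
        tie = tie[kappas >= kappas.max() - 1e-12]
    if len(tie) > 1:
        l1 = np.abs(grid[tie] - np.array([5.0, 15.0, 30.0])).sum(axis=1)
        tie = tie[l1 <= l1.min() + 1e-12]
    k = tie[np.lexsort((grid[tie, 2], grid[tie, 1], grid[tie, 0]))][0]
    return SeverityBoundaries(*[float(v) for v in grid[k]])


def aggregate_boundaries(per_fold: Sequence[SeverityBoundaries]
                         ) -> SeverityBoundaries:
    """Component-wise median over folds (lower median for even counts,
    keeping the result on the search grid)."""
    per_fold = list(per_fold)
    if not per_fold:
        raise ValidationError("no folds to aggregate")
    arr = np.array([b.as_tuple() for b in per_fold])
    lower_median = np.sort(arr, axis=0)[(len(arr) - 1) // 2]
    b1, b2, b3 = (float(v) for v in lower_median)
    if not b1 < b2 < b3:
        table = "\n".join(f"  fold {i}: {tuple(row)}"
                          for i, row in enumerate(arr))
        raise ValidationError(
            f"median boundaries ({b1}, {b2}, {b3}) are not increasing; "
            f"per-fold values:\n{table}")
    return SeverityBoundaries(b1, b2, b3)


# ---------------------------------------------------------------------------
# agreement

@dataclass
class AgreementStats:
    """Cohort-level agreement between estimated and reference AHI/severity."""

    spearman_r: float
    spearman_p: float
    bland_altman_mean_diff: float
    loa_low: float
    loa_high: float
    confusion_4: np.ndarray
    accuracy_4: float
    kappa_4: float
    confusion_2: np.ndarray
    accuracy_2: float
    kappa_2: float
    n_subjects: int


def agreement_stats(assessments: Sequence[SubjectAssessment],
                    collapse_threshold_class: int = 2) -> AgreementStats:
    """Spearman correlation, Bland-Altman agreement and 4-/2-class
    confusion statistics over a cohort."""
    assessments = list(assessments)
    if len(assessments) < 2:
        raise ValidationError("need >= 2 subjects for agreement statistics")
    est = np.array([a.estimated_ahi for a in assessments])
    act = np.array([a.actual_ahi for a in assessments])
    rho, p = spstats.spearmanr(est, act)
    diff = est - act  # estimated minus reference: negative = underestimation
    sd = diff.std()
    true_idx = np.array([_CLASS_INDEX[a.true_class] for a in assessments])
    pred_idx = np.array([_CLASS_INDEX[a.predicted_class] for a in assessments])
    cm4 = confusion_matrix(true_idx, pred_idx, 4)
    acc4, kap4 = accuracy_kappa(cm4)
    t2, p2 = collapse_two_class(true_idx, pred_idx, collapse_threshold_class)
    cm2 = confusion_matrix(t2, p2, 2)
    acc2, kap2 = accuracy_kappa(cm2)
    return AgreementStats(
        spearman_r=float(rho), spearman_p=float(p),
        bland_altman_mean_diff=float(diff.mean()),
        loa_low=float(diff.mean() - 1.96 * sd),
        loa_high=float(diff.mean() + 1.96 * sd),
        confusion_4=cm4, accuracy_4=acc4, kappa_4=kap4,
        confusion_2=cm2, accuracy_2=acc2, kappa_2=kap2,
        n_subjects=len(assessments))


def underestimation_vs_hypopnea(assessments: Sequence[SubjectAssessment],
                                annotations: Dict[str, ApneaAnnotation],
                                recording_hours: Dict[str, float]
                                ) -> Tuple[float, pd.DataFrame]:
    """Spearman correlation between per-subject AHI underestimation
    (actual - estimated) and hypopnea index (hypopneas per recording hour).

    Returns NaN correlation when either variable is constant (flagged
    degenerate case).
    """
    rows = []
    for a in assessments:
        ann = annotations.get(a.subject_id)
        if ann is None:
            raise ValidationError(f"no annotation for {a.subject_id}")
        if any(e.subtype not in
               ("obstructive", "central", "mixed", "hypopnea")
               for e in ann.events):
            raise ValidationError("annotations lack subtype information")
        hours = recording_hours[a.subject_id]
        rows.append({
            "subject_id": a.subject_id,
            "underestimation": a.actual_ahi - a.estimated_ahi,
            "hypopnea_index": ann.hypopnea_index(hours * 3600.0),
        })
    pairs = pd.DataFrame(rows)
    if len(pairs) < 2 or pairs["underestimation"].nunique() < 2 \
            or pairs["hypopnea_index"].nunique() < 2:
        return float("nan"), pairs
    rho, _ = spstats.spearmanr(pairs["underestimation"],
                               pairs["hypopnea_index"])
    return float(rho), pairs
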