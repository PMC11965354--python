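"""Apneic-event classification under leave-one-subject-out cross-validation.

Each fold holds out one subject as the test set; four training subjects —
one per severity class, drawn deterministically from the fold seed — form a
validation set used only for hyperparameter search (seeded random search
maximising validation F1), after which the model is refit on all training
subjects.  Event-detection performance is pooled over subjects: sensitivity
counts true events overlapped by at least one positively-predicted episode,
precision counts positively-predicted episodes overlapping at least one true
event.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .changepoint import events_captured
from .types import (ApneaAnnotation, Episode, FEATURE_NAMES,
                    SEVERITY_CLASSES, ValidationError)

log = logging.getLogger(__name__)

#: hyperparameter search ranges
SEARCH_RANGES = {
    "rf": {"n_trees": (50, 500), "min_leaf_size": (1, 50),
           "positive_prior": (0.1, 0.9)},
    "svm": {"C": (1e-2, 1e2), "gamma": (1e-3, 1e1),
            "positive_prior": (0.1, 0.9)},
    "lr": {"C": (1e-3, 1e3), "positive_prior": (0.1, 0.9)},
}


@dataclass(frozen=True)
class ModelParams:
    algorithm: str = "rf"
    n_trees: int = 200
    min_leaf_size: int = 5
    positive_prior: float = 0.5
    C: float = 1.0
    gamma: float = 0.1

    def __post_init__(self):
        r = SEARCH_RANGES.get(self.algorithm)
        if r is None:
            raise ValidationError(f"unknown algorithm {self.algorithm!r}")
        if self.algorithm == "rf":
            checks = {"n_trees": self.n_trees,
                      "min_leaf_size": self.min_leaf_size,
                      "positive_prior": self.positive_prior}
        elif self.algorithm == "svm":
            checks = {"C": self.C, "gamma": self.gamma,
                      "positive_prior": self.positive_prior}
        else:
            checks = {"C": self.C, "positive_prior": self.positive_prior}
        for k, v in checks.items():
            lo, hi = r[k]
            if not lo <= v <= hi:
                raise ValidationError(
                    f"{self.algorithm} parameter {k}={v} outside [{lo}, {hi}]")


@dataclass
class FoldPlan:
    test_subject_id: str
    train_subject_ids: List[str]
    validation_subject_ids: List[str]
    seed: int = 0

    def __post_init__(self):
        if self.test_subject_id in self.train_subject_ids:
            raise ValidationError("test subject leaked into training set")
        if not set(self.validation_subject_ids) <= set(self.train_subject_ids):
            raise ValidationError("validation subjects must come from training")
        if len(self.validation_subject_ids) != 4:
            raise ValidationError("need exactly one validation subject per "
                                  "severity class")


@dataclass
class EventDetectionMetrics:
    sensitivity: float
    precision: float
    f1: float
    n_true_events: int
    n_captured_events: int
    n_positive_episodes: int
    n_true_positive_episodes: int
    precision_defined: bool = True


def harmonic_f1(sensitivity: float, precision: float) -> float:
    """F1 as the harmonic mean of sensitivity and precision."""
    if sensitivity + precision == 0:
        return 0.0
    return 2.0 * sensitivity * precision / (sensitivity + precision)


def make_fold_plans(subject_classes: Dict[str, str], seed: int = 0
                    ) -> List[FoldPlan]:
    """One leave-one-subject-out fold per subject; validation subjects are
    one randomly-drawn training subject per severity class."""
    subjects = sorted(subject_classes)
    plans = []
    for k, test_id in enumerate(subjects):
        train = [s for s in subjects if s != test_id]
        fold_seed = int(np.random.default_rng([seed, k]).integers(0, 2**31 - 1))
        rng = np.random.default_rng(fold_seed)
        validation = []
        for severity in SEVERITY_CLASSES:
            pool = [s for s in train if subject_classes[s] == severity]
            if not pool:
                raise ValidationError(
                    f"severity class {severity!r} absent from the training "
                    f"set of fold {test_id!r}")
            validation.append(str(rng.choice(pool)))
        plans.append(FoldPlan(test_subject_id=test_id,
                              train_subject_ids=train,
                              validation_subject_ids=validation,
                              seed=fold_seed))
    return plans


def _build_estimator(params: ModelParams, seed: int):
    w = {0: 1.0 - params.positive_prior, 1: params.positive_prior}
    if params.algorithm == "rf":
        return RandomForestClassifier(
            n_estimators=params.n_trees,
            min_samples_leaf=params.min_leaf_size,
            class_weight=w, random_state=seed, n_jobs=1)
    if params.algorithm == "svm":
        return make_pipeline(
            StandardScaler(),
            SVC(C=params.C, gamma=params.gamma, kernel="rbf",
                class_weight=w, random_state=seed))
    return make_pipeline(
        StandardScaler(),
        LogisticRegression(C=params.C, class_weight=w, max_iter=2000,
                           random_state=seed))


def _sample_params(rng: np.random.Generator, algorithm: str) -> ModelParams:
    r = SEARCH_RANGES[algorithm]
    prior = float(rng.uniform(*r["positive_prior"]))
    if algorithm == "rf":
        return ModelParams(
            algorithm="rf",
            n_trees=int(rng.integers(r["n_trees"][0], r["n_trees"][1] + 1)),
            min_leaf_size=int(rng.integers(r["min_leaf_size"][0],
                                           r["min_leaf_size"][1] + 1)),
            positive_prior=prior)
    if algorithm == "svm":
        return ModelParams(
            algorithm="svm",
            C=float(np.exp(rng.uniform(*np.log(r["C"])))),
            gamma=float(np.exp(rng.uniform(*np.log(r["gamma"])))),
            positive_prior=prior)
    return ModelParams(algorithm="lr",
                       C=float(np.exp(rng.uniform(*np.log(r["C"])))),
                       positive_prior=prior)


def _xy(table: pd.DataFrame, subjects: Sequence[str]):
    sel = table[table["subject_id"].isin(list(subjects))]
    return sel[list(FEATURE_NAMES)].to_numpy(), sel["label"].to_numpy(int)


def tune_params(table: pd.DataFrame, train_ids: Sequence[str],
                val_ids: Sequence[str], algorithm: str = "rf",
                budget: int = 30, seed: int = 0) -> ModelParams:
    """Seeded random search over the algorithm's ranges, maximising F1 on
    the validation subjects' episodes; deterministic under ``seed``."""
    fit_ids = [s for s in train_ids if s not in set(val_ids)]
    Xt, yt = _xy(table, fit_ids)
    Xv, yv = _xy(table, val_ids)
    if len(np.unique(yt)) < 2:
        raise ValidationError("training labels are single-class; cannot tune")
    rng = np.random.default_rng(seed)
    best, best_score = None, -1.0
    for k in range(budget):
        params = _sample_params(rng, algorithm)
        est = _build_estimator(params, seed=seed)
        est.fit(Xt, yt)
        score = f1_score(yv, est.predict(Xv), zero_division=0) \
            if len(yv) else 0.0
        if score > best_score:
            best, best_score = params, score
    log.debug("tuned %s: validation F1 %.3f", algorithm, best_score)
    return best


def train_and_predict(fold: FoldPlan, table: pd.DataFrame,
                      params: ModelParams) -> pd.DataFrame:
    """Fit on all training subjects (validation returned to the pool) and
    predict every test-subject episode; returns the test rows with a
    ``prediction`` column."""
    Xt, yt = _xy(table, fold.train_subject_ids)
    test = table[table["subject_id"] == fold.test_subject_id].copy()
    if test.empty:
        log.warning("no valid episodes for %s; predicting none",
                    fold.test_subject_id)
        test["prediction"] = np.array([], dtype=int)
        return test
    if len(np.unique(yt)) < 2:
        test["prediction"] = int(yt[0]) if len(yt) else 0
        return test
    est = _build_estimator(params, seed=fold.seed)
    est.fit(Xt, yt)
    test["prediction"] = est.predict(test[list(FEATURE_NAMES)].to_numpy())
    return test


def pooled_event_metrics(predictions: pd.DataFrame,
                         annotations: Dict[str, ApneaAnnotation]
                         ) -> EventDetectionMetrics:
    """Pool event-level detection counts over all subjects."""
    n_true = n_cap = n_pos = n_tp = 0
    for sid, ann in annotations.items():
        rows = predictions[predictions["subject_id"] == sid]
        eps = [Episode(subject_id=sid, start_s=r.start_s, end_s=r.end_s,
                       prediction=int(r.prediction))
               for r in rows.itertuples()]
        pos = [e for e in eps if e.prediction == 1]
        cap = events_captured(eps, ann, positive_only=True)
        n_true += ann.n_events
        n_cap += int(cap.sum())
        n_pos += len(pos)
        iv = ann.intervals()
        for e in pos:
            if len(iv) and np.any((iv[:, 0] < e.end_s)
                                  & (iv[:, 1] > e.start_s)):
                n_tp += 1
    sens = n_cap / n_true if n_true else 0.0
    if n_pos == 0:
        prec, defined = 0.0, False
    else:
        prec, defined = n_tp / n_pos, True
    return EventDetectionMetrics(
        sensitivity=sens, precision=prec, f1=harmonic_f1(sens, prec),
        n_true_events=n_true, n_captured_events=n_cap,
        n_positive_episodes=n_pos, n_true_positive_episodes=n_tp,
        precision_defined=defined)
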