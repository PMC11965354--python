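"""Cohort-level model and results objects.

:class:`BcgCohortModel` holds a cohort of BCG recordings with their
reference annotations and a :class:`~bcgapnea.types.PipelineConfig`;
``fit()`` runs the full pipeline — signal conditioning, artifact masking,
change-point episode pre-identification, feature extraction,
leave-one-subject-out event classification, AHI estimation and severity
boundary calibration — and returns a :class:`CohortResults` carrying the
per-subject assessments, pooled detection metrics, agreement statistics
before/after boundary adjustment and a ``summary()`` table.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as bio
from .assess import (AgreementStats, adjust_boundaries, agreement_stats,
                     aggregate_boundaries, default_boundary_grid,
                     estimate_ahi, underestimation_vs_hypopnea)
from .changepoint import detect_episodes, label_episodes
from .classify import (EventDetectionMetrics, FoldPlan, make_fold_plans,
                       pooled_event_metrics, train_and_predict, tune_params)
from .features import extract_cohort_features
from .preprocess import preprocess
from .simulate import SubjectSpec, simulate_cohort
from .types import (ApneaAnnotation, BcgRecording, NOMINAL_BOUNDARIES,
                    PipelineConfig, SeverityBoundaries, SubjectAssessment,
                    ValidationError, severity_from_ahi)

log = logging.getLogger(__name__)


class BcgCohortModel:
    """OSAS-assessment model over a cohort of BCG recordings.

    Parameters
    ----------
    recordings : sequence of BcgRecording
    annotations : sequence of ApneaAnnotation
        Reference event annotations, one per recording (matched by
        subject id).
    config : PipelineConfig, optional
    """

    def __init__(self, recordings: Sequence[BcgRecording],
                 annotations: Sequence[ApneaAnnotation],
                 config: Optional[PipelineConfig] = None):
        self.config = (config or PipelineConfig()).validate()
        self.recordings: Dict[str, BcgRecording] = {
            r.subject_id: r for r in recordings}
        self.annotations: Dict[str, ApneaAnnotation] = {
            a.subject_id: a for a in annotations}
        if set(self.recordings) != set(self.annotations):
            raise ValidationError(
                "recordings and annotations name different subjects")
        if len(self.recordings) < len(list(recordings)):
            raise ValidationError("duplicate subject ids in cohort")
        self._feature_table: Optional[pd.DataFrame] = None
        self._stage_counts: Dict[str, dict] = {}

    # -- constructors -------------------------------------------------------
    @classmethod
    def from_directory(cls, path, config: Optional[PipelineConfig] = None
                       ) -> "BcgCohortModel":
        """Load a cohort directory of ``<id>.csv``/``<id>.edf`` signals with
        matching ``<id>_events.csv`` annotation files."""
        path = Path(path)
        recs, anns = [], []
        signals = sorted(list(path.glob("*.csv")) + list(path.glob("*.edf")))
        for sig in signals:
            if sig.name.endswith("_events.csv"):
                continue
            ev = path / f"{sig.stem}_events.csv"
            if not ev.exists():
                raise ValidationError(f"missing annotation file {ev}")
            recs.append(bio.load_recording(sig))
            anns.append(bio.load_annotations(ev))
        if not recs:
            raise ValidationError(f"no cohort signals found under {path}")
        return cls(recs, anns, config=config)

    @classmethod
    def from_simulation(cls, n_per_class: int = 8, duration_h: float = 1.0,
                        seed: int = 0,
                        base_spec: Optional[SubjectSpec] = None,
                        config: Optional[PipelineConfig] = None
                        ) -> "BcgCohortModel":
        """Build the model on a synthetic cohort (one severity class band
        per ``n_per_class`` block)."""
        base = base_spec or SubjectSpec(duration_h=duration_h)
        cohort = simulate_cohort(n_per_class, base_spec=base, seed=seed)
        recs, anns = zip(*cohort)
        return cls(recs, anns, config=config)

    # -- pipeline stages ----------------------------------------------------
    @property
    def subject_ids(self) -> List[str]:
        return sorted(self.recordings)

    def true_classes(self) -> Dict[str, str]:
        out = {}
        for sid in self.subject_ids:
            rec, ann = self.recordings[sid], self.annotations[sid]
            out[sid] = severity_from_ahi(ann.actual_ahi(rec.duration_s))
        return out

    def build_features(self) -> pd.DataFrame:
        """Stages 1-3: conditioning, episode pre-identification, labeling
        and feature extraction; cached after the first call."""
        if self._feature_table is not None:
            return self._feature_table
        cfg = self.config
        all_eps = []
        for sid in self.subject_ids:
            rec = self.recordings[sid]
            proc, mask = preprocess(rec, cfg)
            episodes, counts = detect_episodes(proc, mask, cfg)
            episodes = label_episodes(episodes, self.annotations[sid])
            valid, n_failed = extract_cohort_features(episodes, proc, cfg)
            counts["episodes_built"] = len(episodes)
            counts["feature_failures"] = n_failed
            counts["episodes_valid"] = len(valid)
            counts["episodes_positive"] = sum(e.label == 1 for e in valid)
            counts["artifact_windows_flagged_s"] = sum(
                b - a for a, b in mask.discard_intervals_s)
            self._stage_counts[sid] = counts
            all_eps.extend(valid)
            log.info("subject %s: %d episodes (%d positive)", sid,
                     len(valid), counts["episodes_positive"])
        self._feature_table = bio.feature_table(all_eps)
        return self._feature_table

    def fit(self, seed: Optional[int] = None) -> "CohortResults":
        """Run leave-one-subject-out classification, estimate per-subject
        AHI, calibrate severity boundaries and assemble all statistics."""
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        table = self.build_features()
        classes = self.true_classes()
        plans = make_fold_plans(classes, seed=seed)

        predictions = []
        tuned: Dict[str, object] = {}
        for fold in plans:
            params = tune_params(table, fold.train_subject_ids,
                                 fold.validation_subject_ids,
                                 algorithm=cfg.algorithm,
                                 budget=cfg.tune_budget, seed=fold.seed)
            predictions.append(train_and_predict(fold, table, params))
            tuned[fold.test_subject_id] = params
        predictions = pd.concat(predictions, ignore_index=True)

        est_ahi = {}
        for sid in self.subject_ids:
            rows = predictions[predictions["subject_id"] == sid]
            est_ahi[sid] = estimate_ahi(
                int((rows["prediction"] == 1).sum()),
                self.recordings[sid].duration_s / 3600.0)

        grid = default_boundary_grid(cfg.boundary_b1_grid,
                                     cfg.boundary_b2_grid,
                                     cfg.boundary_b3_grid)
        fold_boundaries = []
        if cfg.adjust_boundaries:
            for fold in plans:
                pairs = [(est_ahi[s], classes[s])
                         for s in fold.train_subject_ids]
                fold_boundaries.append(adjust_boundaries(pairs, grid))
            boundaries = aggregate_boundaries(fold_boundaries)
        else:
            boundaries = NOMINAL_BOUNDARIES

        def make_assessments(bounds: SeverityBoundaries
                             ) -> List[SubjectAssessment]:
            out = []
            for sid in self.subject_ids:
                rec, ann = self.recordings[sid], self.annotations[sid]
                rows = predictions[predictions["subject_id"] == sid]
                out.append(SubjectAssessment(
                    subject_id=sid,
                    estimated_ahi=est_ahi[sid],
                    actual_ahi=ann.actual_ahi(rec.duration_s),
                    predicted_class=severity_from_ahi(est_ahi[sid], bounds),
                    true_class=classes[sid],
                    n_detected_events=int((rows["prediction"] == 1).sum())))
            return out

        assessments = make_assessments(boundaries)
        assessments_nominal = make_assessments(NOMINAL_BOUNDARIES)
        event_metrics = pooled_event_metrics(predictions, self.annotations)
        agreement = agreement_stats(assessments,
                                    cfg.collapse_threshold_class)
        agreement_nominal = agreement_stats(assessments_nominal,
                                            cfg.collapse_threshold_class)
        hours = {sid: self.recordings[sid].duration_s / 3600.0
                 for sid in self.subject_ids}
        hyp_rho, hyp_pairs = underestimation_vs_hypopnea(
            assessments, self.annotations, hours)

        return CohortResults(
            model=self, seed=seed, feature_table=table,
            fold_plans=plans, tuned_params=tuned, predictions=predictions,
            boundaries=boundaries, fold_boundaries=fold_boundaries,
            assessments=assessments, assessments_nominal=assessments_nominal,
            event_metrics=event_metrics, agreement=agreement,
            agreement_nominal=agreement_nominal,
            hypopnea_rho=hyp_rho, hypopnea_pairs=hyp_pairs,
            stage_counts=dict(self._stage_counts))


@dataclass
class CohortResults:
    """Fitted-pipeline results for one cohort."""

    model: BcgCohortModel
    seed: int
    feature_table: pd.DataFrame
    fold_plans: List[FoldPlan]
    tuned_params: Dict[str, object]
    predictions: pd.DataFrame
    boundaries: SeverityBoundaries
    fold_boundaries: List[SeverityBoundaries]
    assessments: List[SubjectAssessment]
    assessments_nominal: List[SubjectAssessment]
    event_metrics: EventDetectionMetrics
    agreement: AgreementStats
    agreement_nominal: AgreementStats
    hypopnea_rho: float
    hypopnea_pairs: pd.DataFrame
    stage_counts: Dict[str, dict]

    def assessment_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(a) for a in self.assessments])

    def metrics_dict(self) -> dict:
        m, a, an = self.event_metrics, self.agreement, self.agreement_nominal
        return {
            "event_detection": vars(m),
            "boundaries_adjusted": self.boundaries.as_tuple(),
            "boundaries_nominal": NOMINAL_BOUNDARIES.as_tuple(),
            "agreement_adjusted": vars(a),
            "agreement_nominal": vars(an),
            "spearman_underestimation_vs_hypopnea_index": self.hypopnea_rho,
            "stage_counts": self.stage_counts,
            "seed": self.seed,
        }

    def save_report(self, path) -> None:
        bio.save_report(self.assessments, self.metrics_dict(), path)

    def summary(self) -> str:
        m, a, an = self.event_metrics, self.agreement, self.agreement_nominal
        b = self.boundaries
        lines = [
            "BCG-based OSAS assessment — cohort results",
            "=" * 58,
            f"subjects: {a.n_subjects}    episodes: {len(self.feature_table)}"
            f"    positive predictions: {m.n_positive_episodes}",
            "",
            "Apneic event detection (pooled over LOSO folds)",
            f"  sensitivity {m.sensitivity:6.3f}   precision "
            f"{m.precision:6.3f}   F1 {m.f1:6.3f}",
            f"  true events {m.n_true_events}   captured "
            f"{m.n_captured_events}",
            "",
            "AHI agreement (estimated vs reference)",
            f"  Spearman r {a.spearman_r:6.3f}   mean difference "
            f"{a.bland_altman_mean_diff:7.2f} events/h",
            f"  95% limits of agreement [{a.loa_low:.2f}, {a.loa_high:.2f}]",
            "",
            f"Severity boundaries: nominal (5, 15, 30) -> adjusted "
            f"({b.b1:g}, {b.b2:g}, {b.b3:g})",
            "  4-class accuracy / kappa:"
            f"  nominal {100 * an.accuracy_4:5.1f}% / {an.kappa_4:.2f}"
            f"   adjusted {100 * a.accuracy_4:5.1f}% / {a.kappa_4:.2f}",
            "  2-class accuracy / kappa:"
            f"  nominal {100 * an.accuracy_2:5.1f}% / {an.kappa_2:.2f}"
            f"   adjusted {100 * a.accuracy_2:5.1f}% / {a.kappa_2:.2f}",
            "",
            f"Underestimation vs hypopnea index: Spearman rho "
            f"{self.hypopnea_rho:.3f}",
        ]
        return "\n".join(lines)

    # -- plots --------------------------------------------------------------
    def plot_ahi_scatter(self, ax=None):
        import matplotlib.pyplot as plt
        ax = ax or plt.gca()
        est = [a.estimated_ahi for a in self.assessments]
        act = [a.actual_ahi for a in self.assessments]
        ax.scatter(act, est, s=24)
        lim = max(max(act), max(est)) * 1.05
        ax.plot([0, lim], [0, lim], "k--", lw=0.8)
        ax.set_xlabel("reference AHI (events/h)")
        ax.set_ylabel("estimated AHI (events/h)")
        ax.set_title(f"Spearman r = {self.agreement.spearman_r:.2f}")
        return ax

    def plot_bland_altman(self, ax=None):
        import matplotlib.pyplot as plt
        ax = ax or plt.gca()
        a = self.agreement
        est = np.array([x.estimated_ahi for x in self.assessments])
        act = np.array([x.actual_ahi for x in self.assessments])
        ax.scatter((est + act) / 2, est - act, s=24)
        for y, style in [(a.bland_altman_mean_diff, "-"),
                         (a.loa_low, ":"), (a.loa_high, ":")]:
            ax.axhline(y, color="k", ls=style, lw=0.8)
        ax.set_xlabel("mean of estimated and reference AHI (events/h)")
        ax.set_ylabel("estimated - reference AHI (events/h)")
        return ax

    def plot_fold_boundaries(self, ax=None):
        import matplotlib.pyplot as plt
        ax = ax or plt.gca()
        arr = np.array([b.as_tuple() for b in self.fold_boundaries])
        if len(arr):
            ax.boxplot([arr[:, 0], arr[:, 1], arr[:, 2]],
                       tick_labels=["b1", "b2", "b3"])
        for y in NOMINAL_BOUNDARIES.as_tuple():
            ax.axhline(y, color="k", ls="--", lw=0.6)
        ax.set_ylabel("AHI boundary (events/h)")
        return ax
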