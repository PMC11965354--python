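"""Shared domain types for the BCG apnea-monitoring pipeline.

All time values are seconds from the start of the recording, 0-based, and
every interval is half-open ``[start, end)``.  "Apneic event" is the umbrella
term for obstructive, central and mixed apnea plus hypopnea.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional

import numpy as np

#: Closed set of annotation subtypes.
SUBTYPES = ("obstructive", "central", "mixed", "hypopnea")

#: Ordinal severity classes, in order.
SEVERITY_CLASSES = ("normal", "mild", "moderate", "severe")

#: Nominal AHI class bands, events/hour: normal [0,5), mild [5,15),
#: moderate [15,30), severe [30, 60].
SEVERITY_BANDS = {
    "normal": (0.0, 5.0),
    "mild": (5.0, 15.0),
    "moderate": (15.0, 30.0),
    "severe": (30.0, 60.0),
}

#: The 38 BCG feature names, in canonical column order (part of the public
#: contract of the feature table).
FEATURE_NAMES = (
    ["Pow", "Sd", "Zcr", "Kurt", "Skew", "TEmean", "TEsd", "SampEn",
     "Int", "Slope", "Res"]
    + [f"AR{k}" for k in range(1, 16)]
    + ["DF1", "DF2", "SP1", "SP2", "SPLmean", "SPLsd", "SPHmean", "SPHsd",
       "VLF", "LF", "HF", "LFHF"]
)
assert len(FEATURE_NAMES) == 38


class ValidationError(ValueError):
    """Raised when a domain invariant is violated."""


class IOFormatError(ValidationError):
    """Raised when a file does not parse or violates an invariant on load."""


@dataclass
class BcgRecording:
    """One subject's single-channel BCG signal.

    Parameters
    ----------
    subject_id : str
    fs : float
        Sampling rate in samples/second (125 for the target device).
    samples : ndarray
        Signal in arbitrary units.
    start_time : str, optional
        ISO timestamp of recording start, if known.
    """

    subject_id: str
    fs: float
    samples: np.ndarray
    start_time: Optional[str] = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if not self.fs > 0:
            raise ValidationError(f"fs must be > 0, got {self.fs}")
        if self.samples.ndim != 1:
            raise ValidationError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("samples contain non-finite values")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    def replace(self, **kw) -> "BcgRecording":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class ApneaEvent:
    onset_s: float
    duration_s: float
    subtype: str

    def __post_init__(self):
        if self.onset_s < 0:
            raise ValidationError(f"onset_s must be >= 0, got {self.onset_s}")
        if not self.duration_s > 0:
            raise ValidationError(
                f"duration_s must be > 0, got {self.duration_s}")
        if self.subtype not in SUBTYPES:
            raise ValidationError(
                f"unknown subtype {self.subtype!r}; expected one of {SUBTYPES}")

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class ApneaAnnotation:
    """Ground-truth apneic-event intervals for one subject.

    Events are stored sorted by onset and must not overlap (half-open
    intervals; touching is allowed).
    """

    subject_id: str
    events: list
    total_sleep_time_s: Optional[float] = None

    def __post_init__(self):
        evs = sorted(self.events, key=lambda e: e.onset_s)
        for a, b in zip(evs, evs[1:]):
            if b.onset_s < a.end_s:  # nonzero-length intersection
                raise ValidationError(
                    f"overlapping events at {a.onset_s}s and {b.onset_s}s "
                    f"for subject {self.subject_id}")
        self.events = evs

    @property
    def n_events(self) -> int:
        return len(self.events)

    def intervals(self) -> np.ndarray:
        """(n, 2) array of [onset, end) seconds."""
        if not self.events:
            return np.empty((0, 2))
        return np.array([[e.onset_s, e.end_s] for e in self.events])

    def actual_ahi(self, recording_duration_s: float) -> float:
        """Events per hour of sleep; falls back to recording time when no
        sleep time is annotated."""
        denom = self.total_sleep_time_s or recording_duration_s
        if not denom > 0:
            raise ValidationError("non-positive time denominator")
        return self.n_events / (denom / 3600.0)

    def hypopnea_index(self, recording_duration_s: float) -> float:
        """Hypopnea events per hour of total recording time."""
        n_hyp = sum(1 for e in self.events if e.subtype == "hypopnea")
        return n_hyp / (recording_duration_s / 3600.0)


@dataclass
class Episode:
    """An apnea-suspected interval produced by change-point detection."""

    subject_id: str
    start_s: float
    end_s: float
    label: Optional[int] = None
    prediction: Optional[int] = None
    features: Optional[dict] = None

    def __post_init__(self):
        if not self.end_s > self.start_s:
            raise ValidationError("episode must have positive duration")
        for name in ("label", "prediction"):
            v = getattr(self, name)
            if v is not None and v not in (0, 1):
                raise ValidationError(f"{name} must be 0/1 when set, got {v}")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class SeverityBoundaries:
    """AHI thresholds separating the four ordinal severity classes."""

    b1: float
    b2: float
    b3: float

    def __post_init__(self):
        if not (0 < self.b1 < self.b2 < self.b3):
            raise ValidationError(
                f"boundaries must satisfy 0 < b1 < b2 < b3, got "
                f"({self.b1}, {self.b2}, {self.b3})")

    def as_tuple(self):
        return (self.b1, self.b2, self.b3)


#: The diagnostic thresholds in routine clinical use (events/hour).
NOMINAL_BOUNDARIES = SeverityBoundaries(5.0, 15.0, 30.0)


@dataclass
class SubjectAssessment:
    """Per-subject outcome of the pipeline."""

    subject_id: str
    estimated_ahi: float
    actual_ahi: float
    predicted_class: str
    true_class: str
    n_detected_events: int = 0

    def __post_init__(self):
        if self.estimated_ahi < 0:
            raise ValidationError("estimated_ahi must be >= 0")
        for name in ("predicted_class", "true_class"):
            if getattr(self, name) not in SEVERITY_CLASSES:
                raise ValidationError(
                    f"{name} must be one of {SEVERITY_CLASSES}")


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with defaults reproducing the
    published settings (0.05–3 Hz order-7 Butterworth, 30 s RMS window,
    1-SD artifact rule, change threshold 50, 10 s minimum episode,
    AR order 15, nominal boundaries 5/15/30)."""

    # preprocess
    band_low_hz: float = 0.05
    band_high_hz: float = 3.0
    filter_order: int = 7
    rms_window_s: float = 30.0
    rms_hop_s: float = 30.0
    artifact_k_sd: float = 1.0
    two_sided: bool = False
    # episode detection
    cp_threshold: float = 50.0
    cp_mode: str = "greedy"            # {"greedy", "exact"}
    cp_min_size: int = 375             # samples; 3 s at 125 Hz
    min_episode_s: float = 10.0
    max_episode_s: float = 120.0
    # features
    ar_order: int = 15
    sampen_m: int = 2
    sampen_r_factor: float = 0.2
    sampen_max_points: int = 2000
    sampen_decimate_above_s: float = 30.0
    welch_segment_s: float = 8.0
    psd_grid_hz: float = 0.01
    trend_mode: str = "signal"         # {"signal", "envelope"}
    sph_on_raw: bool = False
    # classifier
    algorithm: str = "rf"              # {"rf", "svm", "lr"}
    tune_budget: int = 30
    tune_mode: str = "random"          # seeded random search
    # severity boundaries
    boundary_b1_grid: tuple = (0.5, 10.0, 0.5)    # (lo, hi, step)
    boundary_b2_grid: tuple = (0.5, 20.0, 0.5)    # lo is offset above b1
    boundary_b3_grid: tuple = (1.0, 40.0, 1.0)    # lo is offset above b2
    collapse_threshold_class: int = 2  # classes >= this are "moderate+severe"
    adjust_boundaries: bool = True
    # global
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        if not 0 < self.band_low_hz < self.band_high_hz:
            raise ValidationError("need 0 < band_low_hz < band_high_hz")
        if self.cp_mode not in ("greedy", "exact"):
            raise ValidationError(f"unknown cp_mode {self.cp_mode!r}")
        if self.algorithm not in ("rf", "svm", "lr"):
            raise ValidationError(f"unknown algorithm {self.algorithm!r}")
        if self.trend_mode not in ("signal", "envelope"):
            raise ValidationError(f"unknown trend_mode {self.trend_mode!r}")
        if not self.min_episode_s < self.max_episode_s:
            raise ValidationError("need min_episode_s < max_episode_s")
        return self


def severity_from_ahi(ahi: float,
                      boundaries: SeverityBoundaries = NOMINAL_BOUNDARIES
                      ) -> str:
    """Map an AHI to its ordinal class; lower band edges are inclusive."""
    b1, b2, b3 = boundaries.as_tuple()
    if ahi < b1:
        return "normal"
    if ahi < b2:
        return "mild"
    if ahi < b3:
        return "moderate"
    return "severe"
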