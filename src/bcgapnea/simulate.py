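"""Synthetic BCG cohort with ground-truth apnea/hypopnea annotations.

The generator emulates the phenomenology a piezoelectric bed sensor sees: a
cardiac pulse train (damped-oscillation I-J-K-like complex at the heart
rate) whose peak envelope is amplitude-modulated by respiration, riding on
an additive respiratory baseline, plus broadband noise and occasional
high-amplitude motion-artifact bursts.  During an obstructive/central/mixed
apnea the respiratory modulation and baseline are almost fully suppressed;
during a hypopnea they are only partially suppressed; each event is followed
by a few seconds of amplitude overshoot (recovery breaths).

Event scheduling is exact: the annotated event count equals
``round(target_ahi * duration_h)``, durations are uniform on [10, 60] s and
events are separated by at least 15 s, so the annotation-derived event rate
reproduces the subject's target AHI by construction.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Tuple

import numpy as np

from .types import (ApneaAnnotation, ApneaEvent, BcgRecording,
                    SEVERITY_BANDS, SEVERITY_CLASSES, ValidationError)

#: envelope suppression inside full apneas / hypopneas
APNEA_SUPPRESSION = 0.05
HYPOPNEA_SUPPRESSION = (0.3, 0.7)
EVENT_DURATION_S = (10.0, 60.0)
MIN_EVENT_GAP_S = 15.0
EDGE_MARGIN_S = 30.0
RECOVERY_S = (5.0, 10.0)
RECOVERY_GAIN = 1.5


@dataclass
class SubjectSpec:
    """Generation parameters for one synthetic subject.

    ``modulation_depth`` is the fractional respiratory amplitude modulation
    of the cardiac pulses; ``noise_sd`` the additive white-noise SD as a
    fraction of the clean-signal SD; ``artifact_rate`` motion bursts per
    hour; ``hypopnea_fraction`` the fraction of events drawn as hypopneas
    (the remainder are obstructive; central/mixed share the obstructive
    signal phenotype and are not separately modelled).
    """

    severity: str = "normal"
    target_ahi: float = 0.0
    duration_h: float = 8.0
    mean_hr: float = 70.0            # beats/min
    mean_rr_resp: float = 15.0       # breaths/min
    modulation_depth: float = 0.5
    noise_sd: float = 0.1
    artifact_rate: float = 2.0       # bursts/hour
    hypopnea_fraction: float = 0.33
    resp_baseline_amp: float = 0.4   # additive respiration vs pulse amp 1
    seed: int = 0
    subject_id: str = "synthetic"

    def __post_init__(self):
        if self.severity not in SEVERITY_CLASSES:
            raise ValidationError(f"unknown severity {self.severity!r}")
        lo, hi = SEVERITY_BANDS[self.severity]
        if not (lo <= self.target_ahi <= hi):
            raise ValidationError(
                f"target_ahi {self.target_ahi} outside the {self.severity} "
                f"band [{lo}, {hi}]")
        if not 0 <= self.hypopnea_fraction <= 1:
            raise ValidationError("hypopnea_fraction must be in [0, 1]")
        if not self.duration_h > 0:
            raise ValidationError("duration_h must be > 0")


def _pulse_template(fs: float) -> np.ndarray:
    """Damped 8 Hz oscillation (decay 0.15 s) plus a slow recoil bump that
    carries the heart-rate fundamental through a 0.05-3 Hz band-pass."""
    t = np.arange(0.0, 0.6, 1.0 / fs)
    fast = np.exp(-t / 0.15) * np.sin(2 * np.pi * 8.0 * t)
    slow = 0.6 * np.exp(-((t - 0.18) / 0.09) ** 2)
    return fast + slow


def _schedule_events(rng: np.random.Generator, spec: SubjectSpec
                     ) -> List[ApneaEvent]:
    total_s = spec.duration_h * 3600.0
    n_ev = int(round(spec.target_ahi * spec.duration_h))
    if n_ev == 0:
        return []
    durations = rng.uniform(*EVENT_DURATION_S, size=n_ev)
    needed = durations.sum() + MIN_EVENT_GAP_S * (n_ev - 1) + 2 * EDGE_MARGIN_S
    free = total_s - needed
    if free < 0:
        raise ValidationError(
            f"cannot place {n_ev} events of total {durations.sum():.0f}s in "
            f"{total_s:.0f}s at a {MIN_EVENT_GAP_S}s gap; use a longer "
            f"duration_h")
    slack = np.sort(rng.uniform(0.0, free, size=n_ev))
    starts = (EDGE_MARGIN_S + slack
              + np.concatenate([[0.0],
                                np.cumsum(durations[:-1] + MIN_EVENT_GAP_S)]))
    subtypes = np.where(rng.random(n_ev) < spec.hypopnea_fraction,
                        "hypopnea", "obstructive")
    return [ApneaEvent(onset_s=float(s), duration_s=float(d), subtype=str(st))
            for s, d, st in zip(starts, durations, subtypes)]


def simulate_subject(spec: SubjectSpec, fs: float = 125.0,
                     return_details: bool = False):
    """Generate one subject's BCG recording and its ground-truth annotation.

    Deterministic under ``spec.seed``.  With ``return_details`` a third
    element is returned: a dict with the injected artifact intervals
    (seconds) and beat times, for generator-level verification.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_h * 3600.0 * fs))
    t = np.arange(n) / fs

    events = _schedule_events(rng, spec)

    # respiratory waveform with slow (~3%) frequency jitter
    f_resp = spec.mean_rr_resp / 60.0
    n_ctrl = max(2, int(spec.duration_h * 3600.0 / 30.0) + 1)
    ctrl = 1.0 + 0.03 * rng.standard_normal(n_ctrl)
    freq = f_resp * np.interp(t, np.linspace(0, t[-1] if n > 1 else 1, n_ctrl),
                              ctrl)
    resp = np.sin(2 * np.pi * np.cumsum(freq) / fs)

    # respiratory suppression envelope: 1 normally, low inside events,
    # overshoot during recovery breaths
    env = np.ones(n)
    for ev in events:
        i0, i1 = int(ev.onset_s * fs), int(ev.end_s * fs)
        if ev.subtype == "hypopnea":
            env[i0:i1] = rng.uniform(*HYPOPNEA_SUPPRESSION)
        else:
            env[i0:i1] = APNEA_SUPPRESSION
        rec_dur = rng.uniform(*RECOVERY_S)
        i2 = min(n, int((ev.end_s + rec_dur) * fs))
        env[i1:i2] = RECOVERY_GAIN

    # cardiac pulse train, inter-beat interval jitter 5%
    ibi_mean = 60.0 / spec.mean_hr
    n_beats = int(spec.duration_h * 3600.0 / ibi_mean * 1.2) + 8
    ibis = rng.normal(ibi_mean, 0.05 * ibi_mean, size=n_beats)
    ibis = np.clip(ibis, 0.4 * ibi_mean, 1.8 * ibi_mean)
    beat_times = np.cumsum(ibis)
    beat_times = beat_times[beat_times < spec.duration_h * 3600.0 - 0.7]
    template = _pulse_template(fs)
    pulses = np.zeros(n + len(template))
    idx = (beat_times * fs).astype(int)
    np.add.at(pulses, (idx[:, None] + np.arange(len(template))[None, :]),
              template[None, :])
    pulses = pulses[:n]

    clean = (pulses * (1.0 + spec.modulation_depth * resp * env)
             + spec.resp_baseline_amp * resp * env)
    sd_clean = clean.std() or 1.0
    x = clean + spec.noise_sd * sd_clean * rng.standard_normal(n)

    # motion-artifact bursts (kept clear of annotated events)
    n_art = rng.poisson(spec.artifact_rate * spec.duration_h)
    ev_iv = np.array([[e.onset_s, e.end_s] for e in events]) \
        if events else np.empty((0, 2))
    placed = 0
    artifact_intervals = []
    for _ in range(200 * max(1, n_art)):
        if placed >= n_art:
            break
        dur = rng.uniform(2.0, 6.0)
        s0 = rng.uniform(0.0, spec.duration_h * 3600.0 - dur)
        if len(ev_iv) and np.any((ev_iv[:, 0] < s0 + dur + 5)
                                 & (ev_iv[:, 1] > s0 - 5)):
            continue
        i0, i1 = int(s0 * fs), int((s0 + dur) * fs)
        burst = rng.standard_normal(i1 - i0)
        # low-pass shape the burst into the pass band so it survives filtering
        k = max(3, int(0.2 * fs))
        burst = np.convolve(burst, np.hanning(k) / np.hanning(k).sum(),
                            mode="same")
        x[i0:i1] += 6.0 * sd_clean * burst / max(burst.std(), 1e-12)
        artifact_intervals.append((s0, s0 + dur))
        placed += 1

    rec = BcgRecording(subject_id=spec.subject_id, fs=fs, samples=x)
    ann = ApneaAnnotation(subject_id=spec.subject_id, events=events,
                          total_sleep_time_s=spec.duration_h * 3600.0)
    if return_details:
        details = {"artifact_intervals_s": sorted(artifact_intervals),
                   "beat_times_s": beat_times}
        return rec, ann, details
    return rec, ann


def sample_target_ahi(rng: np.random.Generator, severity: str) -> float:
    """Target AHI uniform within the class band, 0.5 events/h inside the
    edges so the rounded realised count stays in band."""
    lo, hi = SEVERITY_BANDS[severity]
    return float(rng.uniform(lo + 0.5, hi - 0.5))


def simulate_cohort(n_per_class: int, base_spec: Optional[SubjectSpec] = None,
                    seed: int = 0, fs: float = 125.0
                    ) -> List[Tuple[BcgRecording, ApneaAnnotation]]:
    """4 * n_per_class subjects, one severity class block at a time, with
    per-subject target AHI sampled inside the class band and per-subject
    seeds derived deterministically from the cohort seed."""
    if n_per_class < 1:
        raise ValidationError("n_per_class must be >= 1")
    base = base_spec or SubjectSpec()
    rng = np.random.default_rng(seed)
    out = []
    k = 0
    for severity in SEVERITY_CLASSES:
        for _ in range(n_per_class):
            k += 1
            spec = replace(
                base, severity=severity,
                target_ahi=sample_target_ahi(rng, severity),
                seed=int(rng.integers(0, 2**31 - 1)),
                subject_id=f"S{k:02d}_{severity}")
            out.append(simulate_subject(spec, fs=fs))
    return out
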