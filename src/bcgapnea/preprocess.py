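"""Signal conditioning: band-pass filtering, z-score normalisation and
RMS-based motion-artifact exclusion.

The fixed stage order is bandpass -> zscore -> rms/artifact-mask.  Filtering
is zero-phase (forward-backward), so apnea onsets are not phase-shifted; the
stated filter order refers to the underlying Butterworth design (effective
order doubles over the two passes).  The artifact rule is one-sided by
default: motion raises RMS amplitude, whereas apneas lower it, and a
two-sided rule would discard the very episodes of interest (a ``two_sided``
flag is retained for sensitivity experiments).  "SD" is the population
(ddof=0) standard deviation throughout.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
from scipy import signal as sps

from .types import BcgRecording, PipelineConfig, ValidationError


@dataclass
class ArtifactMask:
    """Per-sample boolean mask (True = discard) plus the discard intervals
    in seconds; intervals are unions of whole RMS windows."""

    mask: np.ndarray
    discard_intervals_s: List[Tuple[float, float]]

    @property
    def n_flagged(self) -> int:
        return int(self.mask.sum())


def bandpass(rec: BcgRecording, low_hz: float = 0.05, high_hz: float = 3.0,
             order: int = 7) -> BcgRecording:
    """Zero-phase Butterworth band-pass; output length equals input length."""
    if rec.fs <= 2 * high_hz:
        raise ValidationError(
            f"fs={rec.fs} too low for a {high_hz} Hz upper cutoff")
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass",
                     fs=rec.fs, output="sos")
    y = sps.sosfiltfilt(sos, rec.samples)
    return rec.replace(samples=y)


def zscore(rec: BcgRecording) -> BcgRecording:
    x = rec.samples
    sd = x.std()  # population convention
    if sd == 0:
        raise ValidationError("zero-variance signal cannot be z-scored")
    return rec.replace(samples=(x - x.mean()) / sd)


def rms_series(rec: BcgRecording, window_s: float = 30.0,
               hop_s: float | None = None) -> np.ndarray:
    """RMS per window.

    Returns an (n_windows, 2) array of ``(window_start_s, rms)``.  Windows
    are contiguous and non-overlapping by default (hop == window); the last
    partial window is dropped.
    """
    hop_s = window_s if hop_s is None else hop_s
    win = int(round(window_s * rec.fs))
    hop = int(round(hop_s * rec.fs))
    if win < 1 or hop < 1:
        raise ValidationError("window and hop must be >= 1 sample")
    n = len(rec.samples)
    if n < win:
        raise ValidationError(
            f"recording ({rec.duration_s:.1f}s) shorter than one "
            f"{window_s}s RMS window")
    starts = np.arange(0, n - win + 1, hop)
    sq = np.concatenate([[0.0], np.cumsum(rec.samples ** 2)])
    rms = np.sqrt((sq[starts + win] - sq[starts]) / win)
    return np.column_stack([starts / rec.fs, rms])


def artifact_mask(rms: np.ndarray, rec: BcgRecording,
                  k_sd: float = 1.0, window_s: float = 30.0,
                  two_sided: bool = False) -> ArtifactMask:
    """Flag whole RMS windows whose amplitude exceeds mean + k_sd * SD
    (strict inequality; one-sided unless ``two_sided``)."""
    if len(rms) < 2:
        raise ValidationError("need at least 2 RMS windows")
    starts_s, values = rms[:, 0], rms[:, 1]
    mu, sd = values.mean(), values.std()
    flagged = values > mu + k_sd * sd
    if two_sided:
        flagged |= values < mu - k_sd * sd
    mask = np.zeros(len(rec.samples), dtype=bool)
    intervals: List[Tuple[float, float]] = []
    win = int(round(window_s * rec.fs))
    for s, fl in zip(starts_s, flagged):
        if fl:
            i0 = int(round(s * rec.fs))
            mask[i0:i0 + win] = True
            intervals.append((s, min(s + window_s, rec.duration_s)))
    # merge adjacent windows into maximal intervals
    merged: List[Tuple[float, float]] = []
    for iv in intervals:
        if merged and iv[0] <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], iv[1]))
        else:
            merged.append(iv)
    return ArtifactMask(mask=mask, discard_intervals_s=merged)


def preprocess(rec: BcgRecording, cfg: PipelineConfig | None = None
               ) -> tuple[BcgRecording, ArtifactMask]:
    """Full conditioning chain; returns the processed recording and the
    motion-artifact mask."""
    cfg = cfg or PipelineConfig()
    proc = zscore(bandpass(rec, cfg.band_low_hz, cfg.band_high_hz,
                           cfg.filter_order))
    rms = rms_series(proc, cfg.rms_window_s, cfg.rms_hop_s)
    mask = artifact_mask(rms, proc, cfg.artifact_k_sd, cfg.rms_window_s,
                         cfg.two_sided)
    return proc, mask
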