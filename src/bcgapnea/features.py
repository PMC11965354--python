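"""The 38 BCG-only episode features.

Time domain: signal power, SD, zero-crossing rate, kurtosis, skewness,
Teager-energy mean/SD, sample entropy, linear-trend intercept/slope/residual
and 15 autoregressive coefficients.  Frequency domain (Welch PSD, normalised
to unit total power): dominant respiratory (0-0.5 Hz) and cardiac
(0.8-1.8 Hz) frequencies with their peak powers, band statistics over
0-3 Hz and 3-10 Hz, and VLF/LF/HF band powers with the LF/HF ratio.

Episodes vary in length, so every feature is either normalised or a rate;
sample entropy is the only O(n^2) step and long episodes are decimated
(anti-aliased) before it to keep the pipeline cheap.
"""
from __future__ import annotations

import logging
import math
from typing import Optional, Tuple

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats
from statsmodels.regression.linear_model import burg as _burg

from .types import (BcgRecording, Episode, FEATURE_NAMES, PipelineConfig,
                    ValidationError)

log = logging.getLogger(__name__)


class FeatureError(ValidationError):
    """A feature could not be computed for an episode."""


# ---------------------------------------------------------------------------
# time domain

def time_stats(x: np.ndarray) -> Tuple[float, float, float, float, float]:
    """(Pow, Sd, Zcr, Kurt, Skew).

    Pow = mean square, Sd = population SD, Zcr = sign changes per sample
    pair, kurtosis is Fisher (normal -> 0).
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 4:
        raise FeatureError("need >= 4 samples")
    pow_ = float(np.mean(x * x))
    sd = float(np.std(x))
    if sd == 0:
        raise FeatureError("constant signal: moments undefined")
    zcr = float(np.mean(x[:-1] * x[1:] < 0))
    kurt = float(spstats.kurtosis(x, fisher=True, bias=True))
    skew = float(spstats.skew(x, bias=True))
    return pow_, sd, zcr, kurt, skew


def teager_features(x: np.ndarray) -> Tuple[float, float]:
    """Mean and population SD of the Teager energy
    psi[n] = x[n]^2 - x[n-1] * x[n+1]."""
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise FeatureError("need >= 3 samples for the Teager operator")
    psi = x[1:-1] ** 2 - x[:-2] * x[2:]
    return float(psi.mean()), float(psi.std())


def sample_entropy(x: np.ndarray, m: int = 2, r: Optional[float] = None
                   ) -> float:
    """SampEn(m, r) = -log(A/B) with Chebyshev distance, self-matches
    excluded; ``r`` defaults to 0.2 * population SD of ``x``.

    When no template of length m+1 matches (A = 0) the conventional upper
    bound log((N-m)(N-m-1)/2) is returned; B = 0 raises.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 10:
        raise FeatureError("need >= 10 samples for sample entropy")
    if r is None:
        r = 0.2 * float(np.std(x))
    if r <= 0:
        raise FeatureError("tolerance r must be positive")

    nt = n - m  # both template lengths use the same N - m start indices

    def count_matches(mm: int) -> int:
        # templates x[i:i+mm], i = 0..nt-1; count unordered pairs with
        # Chebyshev distance <= r, chunked to bound memory
        total = 0
        chunk = max(1, int(4e6 // nt))
        for i0 in range(0, nt, chunk):
            i1 = min(i0 + chunk, nt)
            d = np.zeros((i1 - i0, nt), dtype=float)
            for k in range(mm):
                d = np.maximum(d, np.abs(x[i0 + k:i1 + k, None]
                                         - x[None, k:k + nt]))
            # exclude self-matches and count each unordered pair once
            total += int((d <= r).sum()) - (i1 - i0)
        return total // 2

    b = count_matches(m)
    a = count_matches(m + 1)
    if b == 0:
        raise FeatureError("no m-length template matches (B = 0)")
    if a == 0:
        nm = n - m
        return float(np.log(nm * (nm - 1) / 2.0))
    return float(-np.log(a / b))


def linear_trend(x: np.ndarray, fs: float, mode: str = "signal"
                 ) -> Tuple[float, float, float]:
    """(Int, Slope, Res): ordinary least squares of the samples (or their
    1 s RMS envelope) against time in seconds; Res is the RMS residual."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise FeatureError("need >= 2 samples")
    if mode == "signal":
        t = np.arange(len(x)) / fs
        y = x
    elif mode == "envelope":
        win = max(1, int(round(fs)))
        nwin = len(x) // win
        if nwin < 2:
            raise FeatureError("episode too short for envelope trend")
        y = np.sqrt((x[:nwin * win].reshape(nwin, win) ** 2).mean(axis=1))
        t = (np.arange(nwin) + 0.5) * win / fs
    else:
        raise ValidationError(f"unknown trend mode {mode!r}")
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    return float(intercept), float(slope), float(np.sqrt(np.mean(resid ** 2)))


def ar_coefficients(x: np.ndarray, order: int = 15) -> np.ndarray:
    """Burg-method AR coefficients, convention
    x[n] = sum_k a_k x[n-k] + e[n]."""
    x = np.asarray(x, dtype=float)
    if len(x) <= 2 * order:
        raise FeatureError(f"need > {2 * order} samples for AR({order})")
    try:
        coeffs, _sigma2 = _burg(x, order=order, demean=True)
    except (ValueError, np.linalg.LinAlgError) as exc:
        raise FeatureError(f"AR fit failed: {exc}") from exc
    if not np.all(np.isfinite(coeffs)):
        raise FeatureError("AR fit produced non-finite coefficients")
    return np.asarray(coeffs, dtype=float)


# ---------------------------------------------------------------------------
# frequency domain

def compute_psd(x: np.ndarray, fs: float, segment_s: float = 8.0,
                grid_hz: float = 0.01):
    """Welch PSD (Hann, 50% overlap, zero-padded to a <= ``grid_hz`` grid).

    Returns (frequencies, normalised power) with the powers summing to 1.
    """
    x = np.asarray(x, dtype=float)
    nperseg = min(len(x), int(round(segment_s * fs)))
    nfft = max(nperseg, int(math.ceil(fs / grid_hz)))
    f, p = sps.welch(x, fs=fs, window="hann", nperseg=nperseg,
                     noverlap=nperseg // 2, nfft=nfft, detrend="constant")
    total = p.sum()
    if total <= 0:
        raise FeatureError("zero spectral power")
    return f, p / total


def _band(f: np.ndarray, lo: float, hi: float, include_lo: bool
          ) -> np.ndarray:
    return ((f >= lo) if include_lo else (f > lo)) & (f <= hi)


def spectral_features(x: np.ndarray, fs: float, segment_s: float = 8.0,
                      grid_hz: float = 0.01) -> dict:
    """DF1/DF2, SP1/SP2, SPL/SPH band statistics and VLF/LF/HF powers from
    the normalised Welch PSD."""
    if len(x) < 8 * fs:
        raise FeatureError("need >= 8 s of signal for spectral features")
    f, p = compute_psd(x, fs, segment_s, grid_hz)

    def peak(lo, hi):
        sel = np.flatnonzero(_band(f, lo, hi, include_lo=True))
        k = sel[np.argmax(p[sel])]
        return float(f[k]), float(p[k])

    df1, sp1 = peak(0.0, 0.5)
    df2, sp2 = peak(0.8, 1.8)
    spl = p[_band(f, 0.0, 3.0, True)]
    sph = p[_band(f, 3.0, 10.0, False)]
    vlf = float(p[_band(f, 0.0, 0.05, True)].sum())
    lf = float(p[_band(f, 0.05, 0.15, False)].sum())
    hf = float(p[_band(f, 0.15, 0.5, False)].sum())
    return {
        "DF1": df1, "DF2": df2, "SP1": sp1, "SP2": sp2,
        "SPLmean": float(spl.mean()), "SPLsd": float(spl.std()),
        "SPHmean": float(sph.mean()) if len(sph) else 0.0,
        "SPHsd": float(sph.std()) if len(sph) else 0.0,
        "VLF": vlf, "LF": lf, "HF": hf,
        "LFHF": float(lf / max(hf, 1e-12)),
    }


# ---------------------------------------------------------------------------
# assembly

def _sampen_input(x: np.ndarray, fs: float, cfg: PipelineConfig
                  ) -> np.ndarray:
    # long episodes are decimated (anti-aliased) before the O(n^2) SampEn
    if len(x) / fs > cfg.sampen_decimate_above_s and \
            len(x) > cfg.sampen_max_points:
        q = int(math.ceil(len(x) / cfg.sampen_max_points))
        return sps.decimate(x, q, ftype="iir", zero_phase=True)
    return x


def extract_features(x: np.ndarray, fs: float,
                     cfg: Optional[PipelineConfig] = None,
                     raw: Optional[np.ndarray] = None) -> dict:
    """All 38 features for one episode's samples.

    ``raw`` optionally supplies the pre-band-pass (z-scored) samples for the
    3-10 Hz band statistics when ``cfg.sph_on_raw`` is set.
    """
    cfg = cfg or PipelineConfig()
    pow_, sd, zcr, kurt, skew = time_stats(x)
    te_mean, te_sd = teager_features(x)
    samp = sample_entropy(_sampen_input(x, fs, cfg), m=cfg.sampen_m,
                          r=cfg.sampen_r_factor * float(np.std(x)))
    intercept, slope, res = linear_trend(x, fs, mode=cfg.trend_mode)
    ar = ar_coefficients(x, order=cfg.ar_order)
    spec = spectral_features(x, fs, cfg.welch_segment_s, cfg.psd_grid_hz)
    if cfg.sph_on_raw and raw is not None:
        spec_raw = spectral_features(raw, fs, cfg.welch_segment_s,
                                     cfg.psd_grid_hz)
        spec["SPHmean"], spec["SPHsd"] = spec_raw["SPHmean"], spec_raw["SPHsd"]
    feats = {"Pow": pow_, "Sd": sd, "Zcr": zcr, "Kurt": kurt, "Skew": skew,
             "TEmean": te_mean, "TEsd": te_sd, "SampEn": samp,
             "Int": intercept, "Slope": slope, "Res": res}
    feats.update({f"AR{k + 1}": float(ar[k]) for k in range(cfg.ar_order)})
    feats.update(spec)
    missing = set(FEATURE_NAMES) - set(feats)
    if missing:
        raise FeatureError(f"missing features {sorted(missing)}")
    if not all(np.isfinite(v) for v in feats.values()):
        raise FeatureError("non-finite feature value")
    return {k: feats[k] for k in FEATURE_NAMES}


def extract_all(episode: Episode, rec: BcgRecording,
                cfg: Optional[PipelineConfig] = None) -> Episode:
    """Attach the 38-feature vector to an episode cut from the conditioned
    recording; raises :class:`FeatureError` when any feature fails."""
    cfg = cfg or PipelineConfig()
    i = int(round(episode.start_s * rec.fs))
    j = int(round(episode.end_s * rec.fs))
    if not (0 <= i < j <= len(rec.samples)):
        raise ValidationError("episode outside recording bounds")
    episode.features = extract_features(rec.samples[i:j], rec.fs, cfg)
    return episode


def extract_cohort_features(episodes, rec: BcgRecording,
                            cfg: Optional[PipelineConfig] = None):
    """Feature extraction over many episodes; invalid episodes are dropped
    (counted and logged), mirroring the per-episode failure contract."""
    cfg = cfg or PipelineConfig()
    valid, n_failed = [], 0
    for ep in episodes:
        try:
            valid.append(extract_all(ep, rec, cfg))
        except ValidationError as exc:
            n_failed += 1
            log.warning("episode %s [%.1f, %.1f)s dropped: %s",
                        ep.subject_id, ep.start_s, ep.end_s, exc)
    return valid, n_failed
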