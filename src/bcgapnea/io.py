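"""File I/O: BCG signals (CSV and single-channel EDF), annotations,
feature tables, assessment reports and pipeline configuration.

CSV signal dialect: one ``value`` column preceded by comment header lines
``# subject_id=...`` and ``# fs=...``.  EDF files carry one signal channel
labelled ``BCG``.  All other artefacts are plain CSV/JSON/YAML.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import yaml

from .types import (ApneaAnnotation, ApneaEvent, BcgRecording, Episode,
                    FEATURE_NAMES, IOFormatError, PipelineConfig,
                    SubjectAssessment, ValidationError)

# ---------------------------------------------------------------------------
# signals

def save_recording_csv(rec: BcgRecording, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# subject_id={rec.subject_id}\n")
        fh.write(f"# fs={rec.fs}\n")
        if rec.start_time:
            fh.write(f"# start_time={rec.start_time}\n")
        fh.write("value\n")
        np.savetxt(fh, rec.samples, fmt="%.9g")


def _load_recording_csv(path: Path) -> BcgRecording:
    meta = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                n_header += 1
                if "=" in line:
                    k, v = line[1:].split("=", 1)
                    meta[k.strip()] = v.strip()
            else:
                break
    if "fs" not in meta:
        raise IOFormatError(f"{path}: missing '# fs=' header line")
    try:
        fs = float(meta["fs"])
    except ValueError:
        raise IOFormatError(f"{path}: unparseable fs {meta['fs']!r}")
    if not fs > 0:
        raise IOFormatError(f"{path}: fs must be > 0, got {fs}")
    df = pd.read_csv(path, comment="#")
    if "value" not in df.columns:
        raise IOFormatError(f"{path}: expected a 'value' column")
    samples = df["value"].to_numpy(dtype=float)
    if not np.all(np.isfinite(samples)):
        raise IOFormatError(f"{path}: samples contain non-finite values")
    return BcgRecording(subject_id=meta.get("subject_id", path.stem),
                        fs=fs, samples=samples,
                        start_time=meta.get("start_time"))


# -- minimal single-channel EDF ---------------------------------------------
# European Data Format: 256-byte fixed header, 256 bytes per signal header,
# then int16 little-endian data records.  One channel, 1-second records.

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def edf_quantization_step(pmin: float, pmax: float) -> float:
    """Physical units per digital step of 16-bit EDF scaling."""
    return (pmax - pmin) / (_EDF_DIG_MAX - _EDF_DIG_MIN)


def save_recording_edf(rec: BcgRecording, path) -> None:
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise IOFormatError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_rec = len(rec.samples) // fs  # whole 1 s records; trailing partial dropped
    if n_rec < 1:
        raise IOFormatError("recording shorter than one EDF data record (1 s)")
    x = rec.samples[:n_rec * fs]
    pmin, pmax = float(x.min()), float(x.max())
    if pmax == pmin:
        pmax = pmin + 1.0
    step = edf_quantization_step(pmin, pmax)
    dig = np.round((x - pmin) / step).astype(np.int64) + _EDF_DIG_MIN
    dig = np.clip(dig, _EDF_DIG_MIN, _EDF_DIG_MAX).astype("<i2")

    def f(s, width):
        s = str(s)[:width]
        return s.ljust(width).encode("ascii")

    hdr = b"".join([
        f("0", 8),                                  # version
        f(rec.subject_id, 80),                      # patient id
        f("BCG recording", 80),                     # recording id
        f("01.01.00", 8), f("00.00.00", 8),         # start date/time
        f(256 + 256, 8),                            # header bytes
        f("", 44),                                  # reserved
        f(n_rec, 8),
        f("1", 8),                                  # record duration (s)
        f("1", 4),                                  # number of signals
    ])
    sig = b"".join([
        f("BCG", 16),
        f("piezoelectric bed sensor", 80),
        f("a.u.", 8),
        f(f"{pmin:.6g}", 8), f(f"{pmax:.6g}", 8),
        f(_EDF_DIG_MIN, 8), f(_EDF_DIG_MAX, 8),
        f("BP:0.05-3Hz", 80),
        f(fs, 8),
        f("", 32),
    ])
    with open(path, "wb") as fh:
        fh.write(hdr + sig)
        fh.write(dig.tobytes())


def _load_recording_edf(path: Path) -> BcgRecording:
    with open(path, "rb") as fh:
        hdr = fh.read(256)
        if len(hdr) < 256:
            raise IOFormatError(f"{path}: truncated EDF header")
        try:
            n_rec = int(hdr[236:244].decode("ascii").strip())
            rec_dur = float(hdr[244:252].decode("ascii").strip())
            n_sig = int(hdr[252:256].decode("ascii").strip())
        except ValueError as exc:
            raise IOFormatError(f"{path}: unparseable EDF header ({exc})")
        if n_sig != 1:
            raise IOFormatError(
                f"{path}: expected a single-channel EDF, got {n_sig} signals")
        sh = fh.read(256)
        label = sh[0:16].decode("ascii").strip()
        pmin = float(sh[104:112].decode("ascii").strip())
        pmax = float(sh[112:120].decode("ascii").strip())
        dmin = int(sh[120:128].decode("ascii").strip())
        dmax = int(sh[128:136].decode("ascii").strip())
        ns_per_rec = int(sh[216:224].decode("ascii").strip())
        subject_id = hdr[8:88].decode("ascii").strip()
        data = np.frombuffer(fh.read(), dtype="<i2")
    expected = n_rec * ns_per_rec
    if len(data) < expected:
        raise IOFormatError(f"{path}: truncated EDF data section")
    data = data[:expected].astype(float)
    scale = (pmax - pmin) / (dmax - dmin)
    samples = (data - dmin) * scale + pmin
    fs = ns_per_rec / rec_dur
    return BcgRecording(subject_id=subject_id or label, fs=fs, samples=samples)


def load_recording(path, format: Optional[str] = None) -> BcgRecording:
    """Load a BCG recording from CSV or EDF.

    ``format`` is inferred from the suffix when not given.
    """
    path = Path(path)
    if not path.exists():
        raise IOFormatError(f"no such file: {path}")
    fmt = format or ("edf" if path.suffix.lower() == ".edf" else "csv")
    if fmt == "csv":
        return _load_recording_csv(path)
    if fmt == "edf":
        return _load_recording_edf(path)
    raise IOFormatError(f"unknown signal format {fmt!r}")


def save_recording(rec: BcgRecording, path, format: Optional[str] = None
                   ) -> None:
    path = Path(path)
    fmt = format or ("edf" if path.suffix.lower() == ".edf" else "csv")
    if fmt == "csv":
        save_recording_csv(rec, path)
    elif fmt == "edf":
        save_recording_edf(rec, path)
    else:
        raise IOFormatError(f"unknown signal format {fmt!r}")


# ---------------------------------------------------------------------------
# annotations

ANNOTATION_COLUMNS = ["subject_id", "onset_s", "duration_s", "subtype"]


def save_annotations(ann: ApneaAnnotation, path) -> None:
    rows = [{"subject_id": ann.subject_id, "onset_s": e.onset_s,
             "duration_s": e.duration_s, "subtype": e.subtype}
            for e in ann.events]
    df = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    with open(path, "w") as fh:
        fh.write(f"# subject_id={ann.subject_id}\n")
        if ann.total_sleep_time_s is not None:
            fh.write(f"# total_sleep_time_s={ann.total_sleep_time_s}\n")
        df.to_csv(fh, index=False)


def load_annotations(path) -> ApneaAnnotation:
    path = Path(path)
    if not path.exists():
        raise IOFormatError(f"no such file: {path}")
    tst, header_sid = None, None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# total_sleep_time_s="):
                tst = float(line.split("=", 1)[1])
            elif line.startswith("# subject_id="):
                header_sid = line.split("=", 1)[1].strip()
    df = pd.read_csv(path, comment="#")
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise IOFormatError(f"{path}: missing columns {sorted(missing)}")
    if df.empty and header_sid is None:
        raise IOFormatError(f"{path}: no events and no subject_id header")
    sids = df["subject_id"].unique() if not df.empty else [header_sid]
    if len(sids) != 1:
        raise IOFormatError(f"{path}: expected one subject, got {list(sids)}")
    try:
        events = [ApneaEvent(onset_s=float(r.onset_s),
                             duration_s=float(r.duration_s),
                             subtype=str(r.subtype))
                  for r in df.itertuples()]
        return ApneaAnnotation(subject_id=str(sids[0]), events=events,
                               total_sleep_time_s=tst)
    except ValidationError as exc:
        raise IOFormatError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# feature tables

EPISODE_COLUMNS = ["subject_id", "start_s", "end_s", "label"]


def feature_table(episodes: Iterable[Episode]) -> pd.DataFrame:
    """One row per episode: id/interval/label + the 38 feature columns."""
    rows = []
    for ep in episodes:
        row = {"subject_id": ep.subject_id, "start_s": ep.start_s,
               "end_s": ep.end_s,
               "label": np.nan if ep.label is None else ep.label}
        feats = ep.features or {}
        for name in FEATURE_NAMES:
            row[name] = feats.get(name, np.nan)
        rows.append(row)
    return pd.DataFrame(rows, columns=EPISODE_COLUMNS + list(FEATURE_NAMES))


def save_feature_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def load_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(EPISODE_COLUMNS + list(FEATURE_NAMES)) - set(df.columns)
    if missing:
        raise IOFormatError(f"{path}: missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# reports

def save_report(assessments, metrics: dict, path) -> None:
    """Write the cohort report (per-subject rows + agreement metrics) as JSON."""
    assessments = list(assessments)
    if not assessments:
        raise ValidationError("cannot save a report with no subjects")

    def jsonable(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: jsonable(v)
                    for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {k: jsonable(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [jsonable(v) for v in obj]
        return obj

    payload = {
        "schema": "bcgapnea-report-1",
        "subjects": [jsonable(a) for a in assessments],
        "metrics": jsonable(metrics),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_report(path) -> dict:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("schema") != "bcgapnea-report-1":
        raise IOFormatError(f"{path}: not a bcgapnea report")
    payload["subjects"] = [SubjectAssessment(**row)
                           for row in payload["subjects"]]
    return payload


# ---------------------------------------------------------------------------
# configuration

def save_config(cfg: PipelineConfig, path) -> None:
    d = dataclasses.asdict(cfg)
    d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    fields = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(d) - fields
    if unknown:
        raise IOFormatError(f"{path}: unknown config keys {sorted(unknown)}")
    d = {k: (tuple(v) if isinstance(v, list) else v) for k, v in d.items()}
    return PipelineConfig(**d).validate()
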