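"""File formats, session alignment and the composed pipeline.

ECG travels as single-channel EDF (physical unit mV).  No EDF writer is
available in the scientific Python stack this package targets, so a minimal
standard-conforming writer lives here; reading goes through MNE, which also
serves as an independent check on the writer.  PPG travels in the
Empatica-export CSV dialect: row 1 the start epoch time, row 2 the sampling
rate, then one sample per row.  Ground truth and reports are JSON; beat,
rate and alarm series are two-column CSV.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import ecg as ecg_mod
from . import ppg as ppg_mod
from .detector import Alarm, DetectorRules, SvmModel, run_detector
from .evaluation import (MatchResult, PerformanceReport, SeizureAnnotation,
                         compute_report, match, merge_alarms)
from .types import RateSeries, WaveformRecord

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# EDF
# --------------------------------------------------------------------------

def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", "replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(path, record: WaveformRecord, channel: str = "ECG",
              physical_dim: str = "mV") -> None:
    """Write a single-channel EDF file (16-bit, 1 s data records).

    The final partial data record is zero-padded; readers see up to one
    extra second of zeros at the end.
    """
    fs = record.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs_i = int(round(fs))
    x = record.samples
    pmax = float(np.max(np.abs(x))) if x.size else 1.0
    if pmax == 0.0:
        pmax = 1.0
    dig_max = 32767
    digital = np.round(x / pmax * dig_max).astype("<i2")
    n_rec = max(1, math.ceil(digital.size / fs_i))
    padded = np.zeros(n_rec * fs_i, dtype="<i2")
    padded[:digital.size] = digital
    with open(path, "wb") as f:
        f.write(_pad("0", 8))
        f.write(_pad("X X X X", 80))                       # patient
        f.write(_pad("Startdate 01-JAN-2000 X X X", 80))   # recording
        f.write(_pad("01.01.00", 8))
        f.write(_pad("00.00.00", 8))
        f.write(_pad(str(256 + 256), 8))                   # header bytes
        f.write(_pad("", 44))
        f.write(_pad(str(n_rec), 8))
        f.write(_pad("1", 8))                              # record duration s
        f.write(_pad("1", 4))                              # one signal
        f.write(_pad(channel, 16))
        f.write(_pad("", 80))                              # transducer
        f.write(_pad(physical_dim, 8))
        f.write(_pad(f"{-pmax:.6g}"[:8], 8))
        f.write(_pad(f"{pmax:.6g}"[:8], 8))
        f.write(_pad(str(-dig_max), 8))
        f.write(_pad(str(dig_max), 8))
        f.write(_pad("", 80))                              # prefiltering
        f.write(_pad(str(fs_i), 8))
        f.write(_pad("", 32))
        f.write(padded.tobytes())


def read_edf(path, channel: str | None = None,
             modality: str = "ecg") -> WaveformRecord:
    """Read one channel of an EDF file via MNE; samples come back in the
    header's physical units (mV for the files this package writes)."""
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"EDF file not found: {path}")
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # corrupt header etc.
        raise ValueError(f"cannot read EDF file {path}: {exc}") from exc
    names = raw.ch_names
    if channel is None:
        channel = names[0]
    if channel not in names:
        raise ValueError(f"channel {channel!r} not in {path} "
                         f"(available: {names})")
    data = raw.get_data(picks=[channel])[0]
    unit = (getattr(raw, "_orig_units", {}) or {}).get(channel, "")
    scale = {"mV": 1e3, "uV": 1e6, "µV": 1e6, "V": 1.0}.get(unit, 1.0)
    return WaveformRecord(data * scale, float(raw.info["sfreq"]), modality)


# --------------------------------------------------------------------------
# CSV dialects
# --------------------------------------------------------------------------

def write_empatica_csv(path, record: WaveformRecord,
                       start_epoch: float = 0.0) -> None:
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow([f"{start_epoch:.6f}"])
        w.writerow([f"{record.fs:.6f}"])
        for v in record.samples:
            w.writerow([f"{v:.9g}"])


def read_empatica_csv(path, modality: str = "ppg") -> WaveformRecord:
    """Empatica export dialect: row 1 start epoch time, row 2 fs, then one
    sample per row."""
    with open(path, newline="") as f:
        rows = [r for r in csv.reader(f) if r]
    if len(rows) < 2:
        raise ValueError(f"{path}: missing header rows (need start epoch on "
                         "row 1 and sampling rate on row 2)")
    try:
        start = float(rows[0][0])
    except ValueError as exc:
        raise ValueError(f"{path}: row 1 is not a start epoch time") from exc
    try:
        fs = float(rows[1][0])
    except ValueError as exc:
        raise ValueError(f"{path}: row 2 is not a sampling rate") from exc
    if len(rows) < 3:
        raise ValueError(f"{path}: empty data section")
    samples = np.array([float(r[0]) for r in rows[2:]])
    rec = WaveformRecord(samples, fs, modality)
    rec.start_epoch = start
    return rec


def write_series_csv(path, times: np.ndarray, values: np.ndarray,
                     header: tuple[str, str] = ("time_s", "value")) -> None:
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(header)
        for t, v in zip(times, values):
            w.writerow([f"{t:.6f}", f"{v:.6f}"])


def read_series_csv(path) -> tuple[np.ndarray, np.ndarray]:
    with open(path, newline="") as f:
        rows = list(csv.reader(f))
    data = np.array([[float(a), float(b)] for a, b in rows[1:]])
    if data.size == 0:
        return np.empty(0), np.empty(0)
    return data[:, 0], data[:, 1]


def write_annotations_csv(path, annotations: list[SeizureAnnotation]) -> None:
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["patient_id", "onset_s", "offset_s"])
        for a in annotations:
            off = "NA" if a.offset is None else f"{a.offset:.3f}"
            w.writerow([a.patient_id, f"{a.onset:.3f}", off])


def read_annotations_csv(path) -> list[SeizureAnnotation]:
    out = []
    with open(path, newline="") as f:
        for row in list(csv.reader(f))[1:]:
            pid, onset, offset = row[0], float(row[1]), row[2]
            out.append(SeizureAnnotation(
                onset, None if offset in ("NA", "") else float(offset), pid))
    return out


def write_ground_truth_json(path, truth) -> None:
    doc = {
        "beat_times_s": [float(t) for t in truth.beat_times],
        "seizure_intervals_s": [[float(a), float(b)]
                                for a, b in truth.seizure_intervals],
        "artifact_intervals_s": {
            mod: [[float(a), float(b), kind] for a, b, kind in ivs]
            for mod, ivs in truth.artifact_intervals.items()},
        "ppg_fiducials_s": [float(t) for t in truth.ppg_fiducials],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


# --------------------------------------------------------------------------
# session alignment
# --------------------------------------------------------------------------

@dataclass
class RecordingManifest:
    """Pointers to one patient's simultaneously recorded files plus the
    clock offsets between the recording systems (user-supplied)."""

    patient_id: str
    ecg_path: str | None = None
    ppg_path: str | None = None
    annotation_path: str | None = None
    offsets: dict[str, float] = field(default_factory=dict)
    interruptions: list[tuple[float, float]] = field(default_factory=list)


def align_recordings(records: dict[str, WaveformRecord],
                     offsets: dict[str, float] | None = None,
                     interruptions: list[tuple[float, float]] | None = None,
                     ) -> tuple[dict[str, WaveformRecord], float]:
    """Restrict all modalities to their common covered span.

    Per-modality clock offsets are applied first; every record is then
    cropped to the intersection of coverage so all systems are evaluated on
    the same data.  Declared interruption intervals are subtracted from the
    evaluated duration (returned in seconds).
    """
    if not records:
        raise ValueError("at least one modality is required")
    offsets = offsets or {}
    shifted = {}
    for mod, rec in records.items():
        off = offsets.get(mod, 0.0)
        shifted[mod] = WaveformRecord(rec.samples, rec.fs, rec.modality,
                                      rec.start_time + off)
    t0 = max(r.start_time for r in shifted.values())
    t1 = min(r.start_time + r.duration for r in shifted.values())
    if t1 <= t0:
        raise ValueError("recordings share no common time span")
    cropped = {}
    for mod, rec in shifted.items():
        i0 = int(round((t0 - rec.start_time) * rec.fs))
        i1 = int(round((t1 - rec.start_time) * rec.fs))
        cropped[mod] = WaveformRecord(rec.samples[i0:i1], rec.fs,
                                      rec.modality, t0)
    evaluated = t1 - t0
    for a, b in interruptions or []:
        lo, hi = max(a, t0), min(b, t1)
        if hi > lo:
            evaluated -= hi - lo
    if evaluated <= 0:
        raise ValueError("interruptions leave no analyzable data")
    return cropped, evaluated


# --------------------------------------------------------------------------
# composed pipeline
# --------------------------------------------------------------------------

def extract_rate(record: WaveformRecord) -> RateSeries:
    """Dispatch to the HRV (ECG) or PRV (PPG) extractor by modality tag."""
    if record.modality == "ecg":
        return ecg_mod.extract_hrv(record)
    return ppg_mod.extract_prv(record)


def run_pipeline(records: dict[str, WaveformRecord],
                 annotations: list[SeizureAnnotation],
                 model: SvmModel,
                 rules: DetectorRules = DetectorRules(),
                 threshold: float | None = None,
                 offsets: dict[str, float] | None = None,
                 interruptions: list[tuple[float, float]] | None = None,
                 ) -> dict[str, dict]:
    """Extract -> detect -> match for every modality over the aligned span.

    Returns, per modality: the match result, merged alarms and the
    evaluated duration in hours.
    """
    aligned, evaluated_s = align_recordings(records, offsets, interruptions)
    out = {}
    for mod, rec in aligned.items():
        rate = extract_rate(rec)
        alarms = run_detector(rate, model, rules, threshold)
        merged = merge_alarms(alarms)
        m = match(merged, annotations)
        log.info("%s: %d rate samples, %d alarms, TP=%d FP=%d",
                 mod, len(rate), len(merged), m.tp, m.fp)
        out[mod] = {"match": m, "alarms": merged,
                    "duration_h": evaluated_s / 3600.0}
    return out


def evaluate_cohort(cohort, model: SvmModel,
                    rules: DetectorRules = DetectorRules(),
                    threshold: float | None = None,
                    modalities: tuple[str, ...] = ("ecg", "ppg"),
                    ) -> dict[str, PerformanceReport]:
    """Run the full chain over a synthetic cohort and score each modality
    against the shared ground-truth annotations."""
    rows: dict[str, list] = {m: [] for m in modalities}
    for pat in cohort:
        ann = [SeizureAnnotation(a, b, pat.patient_id)
               for a, b in pat.truth.seizure_intervals]
        for mod in modalities:
            rec = pat.ecg if mod == "ecg" else pat.ppg
            rate = extract_rate(rec)
            alarms = run_detector(rate, model, rules, threshold)
            m = match(merge_alarms(alarms), ann)
            rows[mod].append((pat.patient_id, m,
                              pat.config.duration / 3600.0))
    return {mod: compute_report(r) for mod, r in rows.items()}
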