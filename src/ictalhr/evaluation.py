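"""Event-level scoring of seizure alarms.

A seizure counts as detected when an alarm falls in its detection window —
the closed interval from 30 s before to 90 s after the annotated onset.
Alarms within 1 min of each other are merged into one before matching.
Sensitivity (Se), false positives per hour (FP/h) and positive predictive
value (PPV) are reported per patient and aggregated two ways: the patient
average (unweighted mean of per-patient values) and the total average
(pooled counts and durations).  Also here: the sensitivity-vs-FA/h curve
over classifier thresholds, sensitivity binned by seizure duration,
missed-seizure attribution on synthetic ground truth, and cross-modality
false-positive coincidence.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .detector import Alarm

log = logging.getLogger(__name__)

DETECTION_WINDOW = (-30.0, 90.0)   # s relative to seizure onset, closed
MERGE_GAP = 60.0                   # s; closer alarms count as one
DURATION_BINS = (0.0, 20.0, 40.0, 60.0, math.inf)
MISS_REASONS = ("HRD", "no HRC", "small HRI", "MA", "Interf", "other")


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up, applied only at presentation time."""
    q = 10.0 ** ndigits
    return math.floor(x * q + 0.5) / q


@dataclass(frozen=True)
class SeizureAnnotation:
    """Ground-truth seizure interval; ``offset`` is None when the seizure
    end could not be determined."""

    onset: float
    offset: float | None = None
    patient_id: str = ""

    def __post_init__(self) -> None:
        if self.offset is not None and self.offset <= self.onset:
            raise ValueError("seizure offset must follow onset")

    @property
    def duration(self) -> float | None:
        return None if self.offset is None else self.offset - self.onset


@dataclass
class MatchResult:
    """Outcome of matching merged alarms against one recording's seizures."""

    detected: list[bool]
    matched_alarm: list[Alarm | None]
    alarm_labels: list[str]          # "TP" | "FP", aligned with input alarms
    seizures: list[SeizureAnnotation]
    alarms: list[Alarm]

    @property
    def tp(self) -> int:
        return sum(self.detected)

    @property
    def fp(self) -> int:
        return sum(1 for lab in self.alarm_labels if lab == "FP")

    @property
    def missed(self) -> int:
        return len(self.detected) - self.tp


@dataclass
class PatientPerformance:
    patient_id: str
    n_seizures: int
    tp: int
    fp: int
    duration_h: float

    @property
    def se(self) -> float | None:
        """Sensitivity in %, undefined for zero-seizure patients."""
        if self.n_seizures == 0:
            return None
        return 100.0 * self.tp / self.n_seizures

    @property
    def fp_per_h(self) -> float:
        return self.fp / self.duration_h

    @property
    def ppv(self) -> float:
        tot = self.tp + self.fp
        return 100.0 * self.tp / tot if tot else 0.0


@dataclass
class PerformanceReport:
    """Per-patient metrics plus both aggregation conventions."""

    per_patient: list[PatientPerformance]

    def total_average(self) -> dict[str, float]:
        tp = sum(p.tp for p in self.per_patient)
        fp = sum(p.fp for p in self.per_patient)
        n = sum(p.n_seizures for p in self.per_patient)
        hours = sum(p.duration_h for p in self.per_patient)
        if hours <= 0:
            raise ValueError("zero total recording duration")
        return {"se": 100.0 * tp / n if n else float("nan"),
                "fp_per_h": fp / hours,
                "ppv": 100.0 * tp / (tp + fp) if tp + fp else 0.0,
                "hours": hours, "n_seizures": n}

    def patient_average(self) -> dict[str, float]:
        se_vals = [p.se for p in self.per_patient if p.se is not None]
        return {"se": float(np.mean(se_vals)) if se_vals else float("nan"),
                "fp_per_h": float(np.mean([p.fp_per_h
                                           for p in self.per_patient])),
                "ppv": float(np.mean([p.ppv for p in self.per_patient]))}


# --------------------------------------------------------------------------
# alarm merging and matching
# --------------------------------------------------------------------------

def merge_alarms(alarms: list[Alarm], gap: float = MERGE_GAP) -> list[Alarm]:
    """Greedy left-to-right merge: an alarm less than ``gap`` seconds after
    the last retained one is absorbed into it (the retained alarm keeps its
    own time and the cluster's maximum score).  Idempotent."""
    out: list[Alarm] = []
    for a in sorted(alarms, key=lambda a: a.time):
        if out and a.time - out[-1].time < gap:
            if a.score > out[-1].score:
                out[-1] = Alarm(out[-1].time, a.score, out[-1].features)
        else:
            out.append(Alarm(a.time, a.score, a.features))
    return out


def match(alarms: list[Alarm], seizures: list[SeizureAnnotation],
          window: tuple[float, float] = DETECTION_WINDOW) -> MatchResult:
    """Assign merged alarms to seizures.

    An alarm inside a seizure's closed detection window detects it; each
    seizure (in onset order, so an alarm eligible for two seizures goes to
    the earlier one) takes its earliest unclaimed in-window alarm.  Matched
    alarms are TP, every other alarm FP.
    """
    seiz = sorted(seizures, key=lambda s: s.onset)
    for s0, s1 in zip(seiz, seiz[1:]):
        if s0.offset is not None and s0.offset > s1.onset:
            raise ValueError(f"overlapping seizure annotations at "
                             f"{s0.onset} and {s1.onset}")
    alarms = sorted(alarms, key=lambda a: a.time)
    claimed = [False] * len(alarms)
    detected, matched = [], []
    for s in seiz:
        hit = None
        for i, a in enumerate(alarms):
            if claimed[i]:
                continue
            if s.onset + window[0] <= a.time <= s.onset + window[1]:
                hit = i
                break
        detected.append(hit is not None)
        matched.append(alarms[hit] if hit is not None else None)
        if hit is not None:
            claimed[hit] = True
    labels = ["TP" if c else "FP" for c in claimed]
    return MatchResult(detected, matched, labels, seiz, alarms)


def compute_report(per_patient: list[tuple[str, MatchResult, float]],
                   ) -> PerformanceReport:
    """Build a report from (patient_id, match result, duration hours)."""
    rows = []
    for pid, m, hours in per_patient:
        if hours <= 0:
            raise ValueError(f"zero-duration recording for patient {pid}")
        rows.append(PatientPerformance(pid, len(m.seizures), m.tp, m.fp,
                                       hours))
    return PerformanceReport(rows)


# --------------------------------------------------------------------------
# threshold sweep and duration bins
# --------------------------------------------------------------------------

def sensitivity_fa_curve(scored: list[tuple[list[Alarm],
                                            list[SeizureAnnotation], float]],
                         thresholds: np.ndarray,
                         ) -> list[tuple[float, float, float]]:
    """(threshold, FA/h, Se) over a sweep of the classifier threshold.

    For each threshold the *unmerged* scored alarms are re-filtered by
    score, re-merged and re-matched, exactly as a full re-evaluation would;
    Se and FA/h are total averages over all recordings.  Both coordinates
    are non-increasing in the threshold.
    """
    out = []
    for tau in np.asarray(thresholds, dtype=float):
        tp = fp = n = 0
        hours = 0.0
        for alarms, seizures, dur_h in scored:
            kept = [a for a in alarms if a.score >= tau]
            m = match(merge_alarms(kept), seizures)
            tp += m.tp
            fp += m.fp
            n += len(seizures)
            hours += dur_h
        se = 100.0 * tp / n if n else float("nan")
        out.append((float(tau), fp / hours if hours else float("nan"), se))
    return out


def sensitivity_by_duration(matches: list[MatchResult],
                            bins: tuple[float, ...] = DURATION_BINS,
                            ) -> list[dict]:
    """Per-duration-bin sensitivity; bins are half-open [lo, hi) with the
    last bin unbounded; unknown-duration seizures are excluded."""
    edges = list(zip(bins[:-1], bins[1:]))
    counts = [[0, 0] for _ in edges]  # [detected, total]
    for m in matches:
        for s, det in zip(m.seizures, m.detected):
            d = s.duration
            if d is None:
                continue
            for k, (lo, hi) in enumerate(edges):
                if lo <= d < hi:
                    counts[k][1] += 1
                    counts[k][0] += int(det)
                    break
    out = []
    for (lo, hi), (det, tot) in zip(edges, counts):
        out.append({"lo": lo, "hi": hi, "n": tot, "detected": det,
                    "se": 100.0 * det / tot if tot else None})
    return out


# --------------------------------------------------------------------------
# missed-seizure attribution and FP coincidence
# --------------------------------------------------------------------------

def attribute_missed(match_result: MatchResult, truth,
                     modality: str,
                     window: tuple[float, float] = DETECTION_WINDOW,
                     ) -> list[str | None]:
    """Reason each missed seizure was missed, on synthetic ground truth.

    Precedence: an artifact interval overlapping the detection window wins
    (motion bursts and dropouts -> "MA"; 50 Hz / 12 Hz tones -> "Interf");
    otherwise the programmed HR response decides — a decrease -> "HRD",
    |delta| < 5 bpm -> "no HRC", an increase under the 20 bpm detectability
    threshold -> "small HRI", anything else -> "other".  Detected seizures
    get None.  Requires generator ground truth; for real recordings the
    reasons must be supplied externally.
    """
    if truth is None or not getattr(truth, "events", ()):
        raise ValueError("missed-seizure attribution needs synthetic ground "
                         "truth; supply reasons externally for real data")
    art = truth.artifact_intervals.get(modality, [])
    kinds_interf = {"powerline_50hz", "narrowband_12hz"}
    reasons: list[str | None] = []
    for s, det in zip(match_result.seizures, match_result.detected):
        if det:
            reasons.append(None)
            continue
        w0, w1 = s.onset + window[0], s.onset + window[1]
        hit = None
        for a, b, kind in art:
            if a <= w1 and b >= w0:
                hit = "Interf" if kind in kinds_interf else "MA"
                break
        if hit is not None:
            reasons.append(hit)
            continue
        ev = min(truth.events, key=lambda e: abs(e.onset - s.onset))
        d = ev.signed_delta
        if d < 0:
            reasons.append("HRD")
        elif abs(d) < 5.0:
            reasons.append("no HRC")
        elif d < 20.0:
            reasons.append("small HRI")
        else:
            reasons.append("other")
    return reasons


def fp_coincidence(fp_by_patient_a: dict[str, list[float]],
                   fp_by_patient_b: dict[str, list[float]],
                   tolerance: float = 60.0) -> dict:
    """Percentage of modality-A false positives with a modality-B false
    positive within ``tolerance`` seconds, per patient; asymmetric in (A, B).

    Patients with no A-side FPs have an undefined percentage and are
    excluded from the mean/SD (with a warning).
    """
    per_patient: dict[str, float | None] = {}
    for pid, fa in fp_by_patient_a.items():
        fb = np.asarray(fp_by_patient_b.get(pid, []), dtype=float)
        if not fa:
            log.warning("patient %s has no FPs in modality A: coincidence "
                        "undefined", pid)
            per_patient[pid] = None
            continue
        hits = sum(1 for t in fa
                   if fb.size and np.min(np.abs(fb - t)) <= tolerance)
        per_patient[pid] = 100.0 * hits / len(fa)
    vals = [v for v in per_patient.values() if v is not None]
    return {"per_patient": per_patient,
            "mean": float(np.mean(vals)) if vals else None,
            "sd": float(np.std(vals)) if vals else None}


# --------------------------------------------------------------------------
# derived-count helpers (arithmetic-consistency checks on published tables)
# --------------------------------------------------------------------------

def sensitivity_from_counts(n_seizures: int, n_missed: int) -> float:
    """Se (%) implied by a total seizure count and a missed count."""
    if not 0 <= n_missed <= n_seizures:
        raise ValueError("missed count outside [0, n_seizures]")
    return 100.0 * (n_seizures - n_missed) / n_seizures


def patient_average(values) -> float:
    """Unweighted mean over patients (the Pat.-av. convention)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("no per-patient values")
    return float(np.mean(arr))
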