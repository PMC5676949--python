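"""Synthetic paired ECG/PPG generator with programmed cardiac dynamics.

Emulates the statistical structure of long-term hospital monitoring of
temporal-lobe-epilepsy patients: a sinus-rhythm baseline with beat-to-beat
variability, seizure events that raise, lower or leave the heart rate
unchanged (ictal tachycardia being the detectable case), motion-artifact
bursts, 50 Hz power-line and ~12 Hz narrowband interference — together with
complete ground truth (beat times, PPG fiducials, seizure and artifact
intervals, the programmed rate trajectory).

The waveform morphologies are parametric templates (a Gaussian-bump QRS
complex with P/T waves for ECG; a gamma-shaped pulse with an abrupt upslope
and rounded peak for PPG).  They are not physiological simulations: their
purpose is to exercise every stage of the fiducial-extraction chain with a
known answer.

Determinism contract: identical (config, seed) yields bit-identical outputs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
from scipy import optimize, signal

from .types import GAP_MAX, GAP_MIN, HR_MAX, HR_MIN, WaveformRecord

log = logging.getLogger(__name__)

# --------------------------------------------------------------------------
# configuration types
# --------------------------------------------------------------------------

HrResponse = Literal["increase", "decrease", "none"]
ArtifactKind = Literal["motion_burst", "powerline_50hz", "narrowband_12hz",
                       "dropout"]

#: default post-ictal recovery time constant, seconds (exponential decay
#: back to baseline after the ictal plateau)
DEFAULT_RECOVERY_TAU = 60.0


@dataclass(frozen=True)
class SimSeizureEvent:
    """One programmed seizure and its heart-rate response.

    Parameters
    ----------
    onset, duration : float
        Seizure interval ``[onset, onset + duration]`` in seconds.
    hr_response : {"increase", "decrease", "none"}
        Direction of the rate change; most temporal-lobe seizures show an
        increase, a minority a decrease or no change.
    delta_hr : float
        Magnitude of the rate change in bpm (>= 0; the sign comes from
        ``hr_response``).  Increases below ~20 bpm are expected to escape
        the detector.
    ramp_time : float
        Seconds from onset to peak (or trough) of the response.
    recovery_tau : float
        Exponential time constant of the post-ictal return to baseline.
    """

    onset: float
    duration: float
    hr_response: HrResponse = "increase"
    delta_hr: float = 30.0
    ramp_time: float = 30.0
    recovery_tau: float = DEFAULT_RECOVERY_TAU

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("seizure duration must be positive")
        if self.delta_hr < 0:
            raise ValueError("delta_hr is a magnitude and must be >= 0")
        if self.ramp_time <= 0:
            raise ValueError("ramp_time must be positive")
        if self.ramp_time > self.duration + 90.0:
            raise ValueError(
                "ramp_time must not outlast the seizure's detection window "
                f"(ramp {self.ramp_time} s > duration {self.duration} + 90 s)")
        if self.hr_response not in ("increase", "decrease", "none"):
            raise ValueError(f"unknown hr_response {self.hr_response!r}")

    @property
    def offset(self) -> float:
        return self.onset + self.duration

    @property
    def signed_delta(self) -> float:
        if self.hr_response == "increase":
            return self.delta_hr
        if self.hr_response == "decrease":
            return -self.delta_hr
        return 0.0


@dataclass(frozen=True)
class ArtifactSpec:
    """Contamination to inject into one modality's waveform.

    ``amplitude`` is relative to the clean signal's peak-to-peak range.
    ``intervals`` must be non-overlapping (start, end) pairs in seconds.
    """

    kind: ArtifactKind
    intervals: tuple[tuple[float, float], ...]
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("motion_burst", "powerline_50hz",
                             "narrowband_12hz", "dropout"):
            raise ValueError(f"unknown artifact kind {self.kind!r}")
        if self.amplitude < 0:
            raise ValueError("artifact amplitude must be >= 0")
        ivs = tuple((float(a), float(b)) for a, b in self.intervals)
        object.__setattr__(self, "intervals", ivs)
        for a, b in ivs:
            if a >= b:
                raise ValueError(f"artifact interval start {a} >= end {b}")
        for (a0, b0), (a1, b1) in zip(ivs, ivs[1:]):
            if b0 > a1:
                raise ValueError("artifact intervals must be non-overlapping")


@dataclass(frozen=True)
class SimConfig:
    """Complete recipe for one synthetic paired ECG+PPG recording."""

    duration: float
    fs_ecg: float = 250.0
    fs_ppg: float = 64.0
    baseline_hr: float = 70.0
    hr_jitter_sd: float = 2.0
    seizures: tuple[SimSeizureEvent, ...] = ()
    artifacts_ecg: tuple[ArtifactSpec, ...] = ()
    artifacts_ppg: tuple[ArtifactSpec, ...] = ()
    pulse_transit_delay: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.fs_ecg <= 0 or self.fs_ppg <= 0:
            raise ValueError("sampling rates must be positive")
        if not 30.0 <= self.baseline_hr <= 180.0:
            raise ValueError("baseline_hr must lie in [30, 180] bpm")
        if self.hr_jitter_sd < 0:
            raise ValueError("hr_jitter_sd must be >= 0")
        object.__setattr__(self, "seizures", tuple(self.seizures))
        object.__setattr__(self, "artifacts_ecg", tuple(self.artifacts_ecg))
        object.__setattr__(self, "artifacts_ppg", tuple(self.artifacts_ppg))
        for ev in self.seizures:
            peak = self.baseline_hr + ev.signed_delta
            if not HR_MIN <= peak <= HR_MAX:
                raise ValueError(
                    f"event at {ev.onset} s drives HR to {peak} bpm, outside "
                    f"[{HR_MIN}, {HR_MAX}]")
        ivals = sorted((ev.onset, ev.offset) for ev in self.seizures)
        for (a0, b0), (a1, b1) in zip(ivals, ivals[1:]):
            if b0 > a1:
                raise ValueError("seizure events must not overlap")


@dataclass
class GroundTruth:
    """Everything the generator knows that a detector must recover."""

    beat_times: np.ndarray
    seizure_intervals: list[tuple[float, float]]
    artifact_intervals: dict[str, list[tuple[float, float, str]]]
    programmed_hr: Callable[[np.ndarray], np.ndarray]
    #: true PPG medium-amplitude-point times (beat + transit delay + template
    #: 50 %-crossing), for fiducial-recovery scoring
    ppg_fiducials: np.ndarray = field(default_factory=lambda: np.empty(0))
    #: the seizure events themselves, for missed-seizure attribution
    events: tuple[SimSeizureEvent, ...] = ()

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        if self.beat_times.size > 1:
            gaps = np.diff(self.beat_times)
            if np.any(gaps <= 0):
                raise ValueError("ground-truth beats must be increasing")
            if np.any(gaps < GAP_MIN - 1e-9) or np.any(gaps > GAP_MAX + 1e-9):
                raise ValueError("ground-truth gaps outside 30-220 bpm band")
        ivs = sorted(self.seizure_intervals)
        for (a0, b0), (a1, b1) in zip(ivs, ivs[1:]):
            if b0 > a1:
                raise ValueError("seizure intervals must be non-overlapping")


# --------------------------------------------------------------------------
# programmed rate trajectory and beat generation
# --------------------------------------------------------------------------

def programmed_hr_function(config: SimConfig) -> Callable[[np.ndarray], np.ndarray]:
    """Noise-free rate trajectory: baseline plus each event's response.

    An event's response rises linearly from 0 to ``delta_hr`` over
    ``ramp_time``, holds until the later of ramp end and seizure offset,
    then decays exponentially with ``recovery_tau`` back to baseline.
    """
    events = config.seizures

    def hr(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, config.baseline_hr)
        for ev in events:
            d = ev.signed_delta
            if d == 0.0:
                continue
            t_peak = ev.onset + ev.ramp_time
            t_rel = max(t_peak, ev.offset)  # release point of the plateau
            shape = np.clip((t - ev.onset) / ev.ramp_time, 0.0, 1.0)
            decay = np.where(t > t_rel,
                             np.exp(-(t - t_rel) / ev.recovery_tau), 1.0)
            out = out + d * shape * decay
        return out

    return hr


def generate_rr_series(config: SimConfig,
                       rng: np.random.Generator | None = None,
                       ) -> tuple[np.ndarray, Callable[[np.ndarray], np.ndarray]]:
    """Generate ground-truth beat times and the programmed HR trajectory.

    Beats are laid down sequentially: at each beat the instantaneous rate is
    the programmed trajectory plus an independent Gaussian perturbation of
    SD ``hr_jitter_sd`` bpm, clamped to the 30-220 bpm physiological band;
    the next beat follows after ``60 / rate`` seconds.
    """
    hr = programmed_hr_function(config)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    beats: list[float] = []
    t = 0.0
    while t < config.duration:
        beats.append(t)
        inst = float(hr(t))
        if config.hr_jitter_sd > 0:
            inst += rng.normal(0.0, config.hr_jitter_sd)
        inst = min(max(inst, HR_MIN), HR_MAX)
        t += 60.0 / inst
    return np.asarray(beats), hr


# --------------------------------------------------------------------------
# waveform templates
# --------------------------------------------------------------------------

def _gauss(t: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - mu) / sd) ** 2)


def ecg_template(tau: np.ndarray, amplitude: float = 1.0) -> np.ndarray:
    """ECG beat template centred on the R-peak (``tau`` = time from beat, s).

    A narrow positive Gaussian R-wave flanked by small Q/S dips, a P bump
    180 ms before and a T bump 280 ms after.  The R-wave dominates every
    other extremum by at least 3x, so the beat fiducial is unambiguous.
    """
    v = (_gauss(tau, 0.0, 0.012)
         - 0.12 * _gauss(tau, -0.028, 0.010)
         - 0.18 * _gauss(tau, 0.030, 0.012)
         + 0.10 * _gauss(tau, -0.18, 0.025)
         + 0.25 * _gauss(tau, 0.28, 0.050))
    return amplitude * v


# PPG pulse: gamma shape  p(tau) = (tau/b)^a * exp(a - tau*a/ (a*b)) ... we
# use tau^a * exp(-tau/b) normalised to unit peak at tau = a*b.
_PPG_A = 2.0
_PPG_B = 0.06


def ppg_template(tau: np.ndarray, amplitude: float = 1.0,
                 a: float = _PPG_A, b: float = _PPG_B) -> np.ndarray:
    """PPG pulse template (``tau`` = time from pulse foot, s).

    Gamma-shaped: zero before the foot, an abrupt monotone upslope to a
    rounded peak at ``tau = a*b`` (120 ms), then an exponential-tailed
    decay that is negligible by the next pulse at physiological rates.
    """
    tau = np.asarray(tau, dtype=float)
    peak = (a * b) ** a * math.exp(-a)
    out = np.where(tau > 0.0, np.power(np.clip(tau, 0.0, None), a)
                   * np.exp(-np.clip(tau, 0.0, None) / b) / peak, 0.0)
    return amplitude * out


def ppg_template_half_rise(a: float = _PPG_A, b: float = _PPG_B) -> float:
    """Time from pulse foot to the 50 %-amplitude point of the upslope.

    Solved numerically on the analytic template; this is the offset between
    a true beat (+ transit delay) and the medium-amplitude-point fiducial.
    """
    t_peak = a * b

    def f(tau: float) -> float:
        return float(ppg_template(np.array([tau]), 1.0, a, b)[0]) - 0.5

    return float(optimize.brentq(f, 1e-6, t_peak))


def synthesize_ecg(beat_times: np.ndarray, fs: float, duration: float,
                   amplitude: float = 1.0) -> WaveformRecord:
    """Render an ECG waveform from beat times by template superposition."""
    if fs < 100.0:
        raise ValueError(f"fs {fs} Hz too low to represent a QRS complex")
    beat_times = np.asarray(beat_times, dtype=float)
    if beat_times.size and np.any(np.diff(beat_times) <= 0):
        raise ValueError("beat times must be strictly increasing")
    n = int(round(duration * fs))
    x = np.zeros(n)
    half = 0.45  # template support, s
    for bt in beat_times:
        i0 = max(0, int(math.ceil((bt - half) * fs)))
        i1 = min(n, int(math.floor((bt + half) * fs)) + 1)
        if i0 >= i1:
            continue
        tau = np.arange(i0, i1) / fs - bt
        x[i0:i1] += ecg_template(tau, amplitude)
    return WaveformRecord(x, fs, "ecg")


def synthesize_ppg(beat_times: np.ndarray, fs: float, duration: float,
                   pulse_transit_delay: float = 0.25,
                   amplitude: float = 1.0) -> WaveformRecord:
    """Render a PPG waveform; each pulse foot sits at beat + transit delay."""
    if fs < 32.0:
        raise ValueError(f"fs {fs} Hz too low to represent a PPG pulse")
    beat_times = np.asarray(beat_times, dtype=float)
    if beat_times.size and np.any(np.diff(beat_times) <= 0):
        raise ValueError("beat times must be strictly increasing")
    n = int(round(duration * fs))
    x = np.zeros(n)
    support = 1.2  # tail length rendered per pulse, s
    for bt in beat_times:
        foot = bt + pulse_transit_delay
        i0 = max(0, int(math.ceil(foot * fs)))
        i1 = min(n, int(math.floor((foot + support) * fs)) + 1)
        if i0 >= i1:
            continue
        tau = np.arange(i0, i1) / fs - foot
        x[i0:i1] += ppg_template(tau, amplitude)
    return WaveformRecord(x, fs, "ppg")


# --------------------------------------------------------------------------
# artifact injection
# --------------------------------------------------------------------------

def inject_artifacts(record: WaveformRecord, spec: ArtifactSpec,
                     seed: int = 0) -> WaveformRecord:
    """Return a copy of ``record`` contaminated per ``spec``.

    Sinusoidal kinds add a 50 Hz (power line) or 12 Hz (narrowband
    interference) tone inside each interval; ``motion_burst`` adds 0.5-8 Hz
    band-limited noise scaled so its peak-to-peak inside the interval equals
    ``amplitude`` x the clean signal's peak-to-peak; ``dropout`` zeroes the
    interval.  Samples outside the intervals are bit-identical to the input.
    """
    x = record.samples.copy()
    n = x.size
    fs = record.fs
    dur = record.duration
    for a, b in spec.intervals:
        if a < 0 or b > dur + 1e-9:
            raise ValueError(f"artifact interval [{a}, {b}] outside record "
                             f"[0, {dur:.3f}]")
    if spec.kind == "powerline_50hz" and fs < 100.0:
        raise ValueError("cannot inject 50 Hz onto a record sampled below "
                         "100 Hz (aliasing)")
    if spec.amplitude == 0.0 and spec.kind != "dropout":
        return WaveformRecord(x, fs, record.modality, record.start_time)
    p2p = float(np.ptp(record.samples)) if n else 0.0
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    for a, b in spec.intervals:
        i0, i1 = int(math.ceil(a * fs)), min(n, int(math.floor(b * fs)) + 1)
        if i0 >= i1:
            continue
        if spec.kind == "dropout":
            x[i0:i1] = 0.0
        elif spec.kind in ("powerline_50hz", "narrowband_12hz"):
            f0 = 50.0 if spec.kind == "powerline_50hz" else 12.0
            x[i0:i1] += (0.5 * spec.amplitude * p2p
                         * np.sin(2 * np.pi * f0 * t[i0:i1]))
        else:  # motion_burst
            noise = rng.standard_normal(i1 - i0)
            if i1 - i0 > 30:  # band-limit to 0.5-8 Hz where possible
                nyq = fs / 2.0
                hi = min(8.0, 0.9 * nyq)
                sos = signal.butter(2, [0.5 / nyq, hi / nyq], "bandpass",
                                    output="sos")
                noise = signal.sosfiltfilt(sos, noise)
            span = float(np.ptp(noise))
            if span > 0:
                noise *= spec.amplitude * p2p / span
            x[i0:i1] += noise
    return WaveformRecord(x, fs, record.modality, record.start_time)


# --------------------------------------------------------------------------
# full-record and cohort generation
# --------------------------------------------------------------------------

@dataclass
class PatientRecord:
    """One synthetic patient: paired waveforms plus complete ground truth."""

    patient_id: str
    ecg: WaveformRecord
    ppg: WaveformRecord
    truth: GroundTruth
    config: SimConfig


def generate_record(config: SimConfig) -> tuple[WaveformRecord,
                                                WaveformRecord, GroundTruth]:
    """Generate one paired ECG+PPG recording with ground truth."""
    rng = np.random.default_rng(config.seed)
    beats, hr = generate_rr_series(config, rng)
    ecg = synthesize_ecg(beats, config.fs_ecg, config.duration)
    ppg = synthesize_ppg(beats, config.fs_ppg, config.duration,
                         config.pulse_transit_delay)
    art_ivals: dict[str, list[tuple[float, float, str]]] = {"ecg": [],
                                                            "ppg": []}
    for k, spec in enumerate(config.artifacts_ecg):
        ecg = inject_artifacts(ecg, spec, seed=config.seed * 1000 + k)
        art_ivals["ecg"] += [(a, b, spec.kind) for a, b in spec.intervals]
    for k, spec in enumerate(config.artifacts_ppg):
        ppg = inject_artifacts(ppg, spec, seed=config.seed * 1000 + 500 + k)
        art_ivals["ppg"] += [(a, b, spec.kind) for a, b in spec.intervals]
    t50 = ppg_template_half_rise()
    fid = beats + config.pulse_transit_delay + t50
    fid = fid[fid < config.duration]
    truth = GroundTruth(
        beat_times=beats,
        seizure_intervals=[(ev.onset, ev.offset) for ev in config.seizures],
        artifact_intervals=art_ivals,
        programmed_hr=hr,
        ppg_fiducials=fid,
        events=config.seizures,
    )
    return ecg, ppg, truth


def generate_cohort(n_patients: int, seed: int, *,
                    duration: float = 600.0,
                    seizure_counts: Sequence[int] | None = None,
                    delta_hr: float = 30.0,
                    ramp_time: float = 30.0,
                    seizure_duration: float = 60.0,
                    hr_response: HrResponse = "increase",
                    baseline_hr_range: tuple[float, float] = (60.0, 80.0),
                    hr_jitter_sd: float = 2.0,
                    ppg_motion_on_seizures: bool = False,
                    motion_amplitude: float = 2.0,
                    ) -> list[PatientRecord]:
    """Generate a desk-scale cohort of paired recordings.

    Per-patient sub-streams are spawned deterministically from ``seed``;
    seizures are placed with at least 150 s of clean margin on each side so
    every event has a full baseline window and detection window inside the
    record.  ``ppg_motion_on_seizures`` covers each seizure's detection
    window with a motion burst on the PPG channel only — the mechanism by
    which wrist-worn PPG loses seizures that ECG keeps.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if seizure_counts is not None and len(seizure_counts) != n_patients:
        raise ValueError("seizure_counts length must equal n_patients")
    ss = np.random.SeedSequence(seed)
    out: list[PatientRecord] = []
    for p, child in enumerate(ss.spawn(n_patients)):
        sub = np.random.default_rng(child)
        n_seiz = 1 if seizure_counts is None else int(seizure_counts[p])
        base = float(sub.uniform(*baseline_hr_range))
        margin = 150.0
        events = []
        if n_seiz > 0:
            slot = (duration - 2 * margin) / n_seiz
            if slot < seizure_duration + 90.0:
                raise ValueError("record too short for requested seizures")
            for s in range(n_seiz):
                lo = margin + s * slot
                hi = lo + slot - seizure_duration - 90.0
                onset = float(sub.uniform(lo, hi))
                events.append(SimSeizureEvent(
                    onset=onset, duration=seizure_duration,
                    hr_response=hr_response, delta_hr=delta_hr,
                    ramp_time=ramp_time))
        artifacts_ppg: tuple[ArtifactSpec, ...] = ()
        if ppg_motion_on_seizures and events:
            ivs = tuple((max(0.0, ev.onset - 40.0),
                         min(duration, ev.offset + 90.0)) for ev in events)
            artifacts_ppg = (ArtifactSpec("motion_burst", ivs,
                                          motion_amplitude),)
        cfg = SimConfig(
            duration=duration, baseline_hr=base, hr_jitter_sd=hr_jitter_sd,
            seizures=tuple(events), artifacts_ppg=artifacts_ppg,
            seed=int(child.generate_state(1)[0] % (2 ** 31)))
        ecg, ppg, truth = generate_record(cfg)
        out.append(PatientRecord(f"sim{p + 1:02d}", ecg, ppg, truth, cfg))
    return out
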