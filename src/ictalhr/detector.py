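"""Online ictal-tachycardia detection from a heart/pulse rate series.

The detector scans the (median-filtered) rate series causally for a heart
rate rise of at least 20 bpm above the pre-rise baseline that completes
within 60 s and is sustained for at least 10 s.  For each such event three
features are extracted — the peak rate HRpeak, and the mean and standard
deviation of the rate over the 60 s baseline window before the rise — and a
Gaussian-kernel support-vector machine scores the event; alarms are events
whose score clears the decision threshold.

Every decision uses only samples at or before the alarm time, so truncating
the series at any time and re-running reproduces exactly the alarms up to
that time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import joblib
import numpy as np
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .types import HR_MAX, HR_MIN, RateSeries, beats_to_rate

log = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class DetectorRules:
    """Rule stage constants (all configurable; bpm and seconds).

    ``min_increase`` is the detectability threshold: rises smaller than
    20 bpm are below it by design, which is why small ictal HR increases are
    missed.  The baseline is the trailing window ending ``max_ramp`` before
    the current sample so the rise itself never contaminates it.
    """

    min_increase: float = 20.0
    max_ramp: float = 60.0
    min_hold: float = 10.0
    baseline_len: float = 60.0
    refractory: float = 60.0
    median_kernel: int = 5
    #: use the past-samples-only median filter (strict online mode)
    causal_filter: bool = False


@dataclass
class HrIncreaseEvent:
    """A candidate ictal HR rise found by the rule stage."""

    start_time: float   # last baseline-level sample before the rise
    peak_time: float    # end of the rise (= alarm time if classified)
    baseline_mean: float

    def __post_init__(self) -> None:
        if self.peak_time <= self.start_time:
            raise ValueError("peak_time must follow start_time")


@dataclass(frozen=True)
class DetectorFeatures:
    """The three classification features of one event."""

    hr_peak: float
    hr_base_mean: float
    hr_base_std: float

    def as_array(self) -> np.ndarray:
        return np.array([self.hr_peak, self.hr_base_mean, self.hr_base_std])


@dataclass
class Alarm:
    time: float
    score: float
    features: DetectorFeatures | None = None


# --------------------------------------------------------------------------
# rate-series conditioning
# --------------------------------------------------------------------------

def filter_rate(series: RateSeries, kernel: int = 5,
                causal: bool = False) -> RateSeries:
    """Median filter (edge-truncated) then plausibility clamp.

    The centred window uses ``kernel`` samples; the causal variant uses only
    the current and previous ``kernel - 1`` samples, for online use.
    Samples outside [30, 220] bpm after filtering are dropped.
    """
    if len(series) == 0:
        return series
    r = series.rates
    n = r.size
    out = np.empty(n)
    h = kernel // 2
    for i in range(n):
        if causal:
            lo, hi = max(0, i - kernel + 1), i + 1
        else:
            lo, hi = max(0, i - h), min(n, i + h + 1)
        out[i] = np.median(r[lo:hi])
    ok = (out >= HR_MIN) & (out <= HR_MAX)
    return RateSeries(series.times[ok], out[ok], series.source_modality)


# --------------------------------------------------------------------------
# rule stage
# --------------------------------------------------------------------------

def detect_hr_increase(series: RateSeries,
                       rules: DetectorRules = DetectorRules(),
                       ) -> list[HrIncreaseEvent]:
    """Online scan for sustained HR rises.

    At sample i the baseline is the mean rate over the window
    ``[t_i - max_ramp - baseline_len, t_i - max_ramp)`` — i.e. the 60 s that
    ended where the fastest admissible ramp could have started.  A crossing
    occurs when the current rate exceeds baseline + ``min_increase``.  The
    event is confirmed once the rate has stayed above that level for
    ``min_hold`` seconds and has stopped rising; ``peak_time`` is the
    confirming sample, so confirmation uses no future data.  ``start_time``
    is the last pre-crossing sample at baseline level (within half the
    increase threshold).  A 60 s refractory suppresses re-triggering on the
    same plateau.
    """
    t, r = series.times, series.rates
    n = t.size
    if n == 0 or t[-1] - t[0] < 120.0:
        log.warning("rate series shorter than 120 s: no events")
        return []
    events: list[HrIncreaseEvent] = []
    suppressed_until = -np.inf
    i = 0
    while i < n:
        ti = t[i]
        if ti < suppressed_until:
            i += 1
            continue
        j1 = int(np.searchsorted(t, ti - rules.max_ramp))
        j0 = int(np.searchsorted(t, ti - rules.max_ramp - rules.baseline_len))
        if j1 - j0 < 1:
            i += 1
            continue
        base = float(np.mean(r[j0:j1]))
        level = base + rules.min_increase
        if r[i] < level:
            i += 1
            continue
        # --- crossing at sample i: locate the start of the rise
        k = i - 1
        start_idx = None
        while k >= 0 and ti - t[k] <= rules.max_ramp + 1.0:
            if r[k] <= base + 0.25 * rules.min_increase:
                start_idx = k
                break
            k -= 1
        if start_idx is None or ti - t[start_idx] > rules.max_ramp:
            i += 1
            continue
        # --- hold-and-peak confirmation
        cross_t = ti
        run_max = r[i]
        j = i + 1
        confirmed = None
        while j < n:
            if r[j] < level:       # fell back before confirmation
                break
            if t[j] - cross_t >= rules.min_hold and r[j] <= run_max:
                confirmed = j
                break
            run_max = max(run_max, r[j])
            j += 1
        if confirmed is None:
            i = j + 1
            continue
        events.append(HrIncreaseEvent(start_time=float(t[start_idx]),
                                      peak_time=float(t[confirmed]),
                                      baseline_mean=base))
        suppressed_until = t[confirmed] + rules.refractory
        i = confirmed + 1
    return events


def extract_features(series: RateSeries, event: HrIncreaseEvent,
                     baseline_len: float = 60.0,
                     min_baseline_samples: int = 5,
                     ) -> DetectorFeatures | None:
    """HRpeak (rate at peak_time) and the baseline window's mean/SD
    (population form) over ``[start - 60, start)``; events whose baseline
    window holds fewer than 5 samples are discarded."""
    t, r = series.times, series.rates
    ip = int(np.searchsorted(t, event.peak_time))
    if ip >= t.size or not np.isclose(t[ip], event.peak_time):
        ip = min(t.size - 1, max(0, ip - 1))
    hr_peak = float(r[ip])
    j0 = int(np.searchsorted(t, event.start_time - baseline_len))
    j1 = int(np.searchsorted(t, event.start_time))
    window = r[j0:j1]
    if window.size < min_baseline_samples:
        log.debug("event at %.1f s discarded: %d baseline samples",
                  event.peak_time, window.size)
        return None
    return DetectorFeatures(hr_peak, float(np.mean(window)),
                            float(np.std(window)))


# --------------------------------------------------------------------------
# SVM classification
# --------------------------------------------------------------------------

@dataclass
class SvmModel:
    """Gaussian-kernel SVM over z-standardised features.

    The standardisation parameters and kernel width are stored with the
    support data, so scoring is deterministic and the model round-trips
    bit-exactly through :func:`save_model` / :func:`load_model`.
    """

    svc: SVC
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    threshold: float = 0.0
    version: int = MODEL_FORMAT_VERSION

    def score(self, features: DetectorFeatures) -> float:
        x = (features.as_array() - self.scaler_mean) / self.scaler_scale
        return float(self.svc.decision_function(x[None, :])[0])


def train_model(features: list[DetectorFeatures], labels: list[int] | np.ndarray,
                C: float = 1.0, gamma: float | None = None) -> SvmModel:
    """Fit the Gaussian-kernel SVM.

    Features are z-standardised; the default kernel width follows the
    median-pairwise-distance heuristic (gamma = 1 / (2 * median_dist^2)).
    Training is deterministic given the input order and hyperparameters.
    """
    y = np.asarray(labels, dtype=int)
    if len(features) != y.size:
        raise ValueError("features and labels must have equal length")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("training needs both classes present")
    if counts.min() < 5:
        raise ValueError("training needs at least 5 examples per class")
    X = np.vstack([f.as_array() for f in features])
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    if gamma is None:
        from scipy.spatial.distance import pdist
        med = float(np.median(pdist(Xs)))
        gamma = 1.0 / (2.0 * med * med) if med > 0 else 1.0
    svc = SVC(C=C, kernel="rbf", gamma=gamma)
    svc.fit(Xs, y)
    return SvmModel(svc, scaler.mean_.copy(), scaler.scale_.copy())


def classify(model: SvmModel, features: DetectorFeatures,
             threshold: float | None = None) -> tuple[bool, float]:
    """Score one event; seizure iff score >= threshold.  The score does not
    depend on the threshold, so threshold sweeps reuse the same scores."""
    thr = model.threshold if threshold is None else threshold
    s = model.score(features)
    return s >= thr, s


def save_model(model: SvmModel, path) -> None:
    joblib.dump({"format_version": model.version, "svc": model.svc,
                 "scaler_mean": model.scaler_mean,
                 "scaler_scale": model.scaler_scale,
                 "threshold": model.threshold}, path)


def load_model(path) -> SvmModel:
    d = joblib.load(path)
    if d.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format {d.get('format_version')}")
    return SvmModel(d["svc"], d["scaler_mean"], d["scaler_scale"],
                    d["threshold"])


# --------------------------------------------------------------------------
# full detector
# --------------------------------------------------------------------------

def run_detector(series: RateSeries, model: SvmModel,
                 rules: DetectorRules = DetectorRules(),
                 threshold: float | None = None) -> list[Alarm]:
    """filter -> rule stage -> features -> SVM; one alarm per accepted
    event, timestamped at the event's peak."""
    filtered = filter_rate(series, rules.median_kernel,
                           causal=rules.causal_filter)
    events = detect_hr_increase(filtered, rules)
    alarms: list[Alarm] = []
    for ev in events:
        feats = extract_features(filtered, ev, rules.baseline_len)
        if feats is None:
            continue
        is_seiz, score = classify(model, feats, threshold)
        if is_seiz:
            alarms.append(Alarm(ev.peak_time, score, feats))
    log.info("%d events -> %d alarms", len(events), len(alarms))
    return alarms


def score_all_events(series: RateSeries, model: SvmModel,
                     rules: DetectorRules = DetectorRules()) -> list[Alarm]:
    """Every rule-stage event with its SVM score, regardless of threshold —
    the input to sensitivity/false-alarm threshold sweeps."""
    return run_detector(series, model, rules, threshold=-np.inf)


# --------------------------------------------------------------------------
# synthetic training cohort
# --------------------------------------------------------------------------

def make_training_set(seed: int, n_per_class: int = 40,
                      ) -> tuple[list[DetectorFeatures], np.ndarray]:
    """Harvest labelled features from seeded synthetic rate series.

    Positives are ictal rises: 22-45 bpm ramps over 20-50 s on a quiet
    baseline (beat-to-beat SD 1-3 bpm).  Negatives are exercise-like rises
    of 20-32 bpm over 40-60 s on a restless baseline (SD 5-9 bpm) — the
    non-ictal HR increases that cause false alarms.  The classes separate
    mainly on baseline variability and rise magnitude.
    """
    from .synthetic import SimConfig, SimSeizureEvent, generate_rr_series
    from .types import BeatSeries

    rng = np.random.default_rng(seed)
    feats: list[DetectorFeatures] = []
    labels: list[int] = []
    rules = DetectorRules()
    for label in (1, 0):
        made = 0
        attempt = 0
        while made < n_per_class and attempt < n_per_class * 4:
            attempt += 1
            if label == 1:
                delta = float(rng.uniform(22, 45))
                ramp = float(rng.uniform(20, 50))
                jitter = float(rng.uniform(1, 3))
            else:
                delta = float(rng.uniform(20, 32))
                ramp = float(rng.uniform(40, 60))
                jitter = float(rng.uniform(5, 9))
            base = float(rng.uniform(55, 85))
            ev = SimSeizureEvent(onset=180.0, duration=60.0,
                                 hr_response="increase", delta_hr=delta,
                                 ramp_time=ramp)
            cfg = SimConfig(duration=420.0, baseline_hr=base,
                            hr_jitter_sd=jitter, seizures=(ev,),
                            seed=int(rng.integers(2 ** 31)))
            beats, _ = generate_rr_series(cfg)
            rate = filter_rate(beats_to_rate(BeatSeries(beats, "ecg")),
                               rules.median_kernel)
            for event in detect_hr_increase(rate, rules):
                if abs(event.peak_time - (ev.onset + ev.ramp_time)) > 90:
                    continue
                f = extract_features(rate, event, rules.baseline_len)
                if f is not None:
                    feats.append(f)
                    labels.append(label)
                    made += 1
                    break
        if made < n_per_class:
            log.warning("training class %d: only %d/%d examples harvested",
                        label, made, n_per_class)
    return feats, np.asarray(labels)


def train_default_model(seed: int = 12345, n_per_class: int = 40) -> SvmModel:
    """Train the shipped substitute classifier on the seeded synthetic
    training cohort (the original clinical training data is not public)."""
    feats, labels = make_training_set(seed, n_per_class)
    return train_model(feats, labels)
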