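"""Pulse detection and PRV extraction from wrist PPG.

Two phases: a linear-phase FIR low-pass-differentiator accentuates the
abrupt pulse upslopes, whose peaks are found by an adaptive thresholding
pass; each upslope is then anchored in the raw signal (pulse foot before,
pulse maximum after) and the beat fiducial is the medium-amplitude point —
the instant on the upslope where the signal has risen to 50 % of the
foot-to-peak amplitude, located by linear interpolation.  The 50 % point is
the most timing-stable landmark of the pulse, hence the most precise PRV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import signal

from .types import BeatSeries, RateSeries, WaveformRecord, beats_to_rate

log = logging.getLogger(__name__)

DIFF_PASSBAND = 7.0     # Hz — pulse upslope energy lives below ~8 Hz
DIFF_STOPBAND = 11.0    # Hz
DEFAULT_REFRACTORY = 0.30   # s (200 bpm ceiling)
SEARCH_WINDOW = 0.40        # s, foot/maximum search around an upslope peak
THRESH_FACTOR = 0.5
THRESH_DECAY = 0.125        # EW-mean decay ~ last 8 accepted peaks
SILENCE_REINIT = 3.0        # s without detections before re-initialising


@dataclass
class FilteredPpg:
    """Low-pass-differentiated PPG, group delay compensated (same length
    and time base as the input record)."""

    samples: np.ndarray
    fs: float
    start_time: float = 0.0


@dataclass
class PulseFiducials:
    """Per-pulse landmarks, index-aligned across arrays."""

    upslope_peak_times: np.ndarray
    foot_times: np.ndarray
    max_times: np.ndarray
    map_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    amplitudes: np.ndarray = field(default_factory=lambda: np.empty(0))
    #: sample indices of foot/max in the raw record (internal plumbing)
    foot_idx: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    max_idx: np.ndarray = field(default_factory=lambda: np.empty(0, int))


@lru_cache(maxsize=8)
def _differentiator_taps(fs: float) -> np.ndarray:
    """Linear-phase FIR low-pass differentiator (type III, odd length).

    Passband edge 7 Hz, stopband 11 Hz, ~fs/2 taps; the taps are rescaled so
    the passband gain matches the true derivative (2*pi*f) at 1 Hz.
    """
    numtaps = int(round(fs / 2))
    if numtaps % 2 == 0:
        numtaps += 1
    numtaps = max(numtaps, 21)
    taps = signal.remez(numtaps, [0.0, DIFF_PASSBAND, DIFF_STOPBAND, fs / 2],
                        [1.0, 0.0], type="differentiator", fs=fs)
    w, h = signal.freqz(taps, worN=[2 * np.pi * 1.0 / fs])
    taps = taps * (2 * np.pi * 1.0 / abs(h[0]))
    return taps


def lowpass_differentiate(record: WaveformRecord) -> FilteredPpg:
    """Apply the low-pass differentiator with exact integer-delay
    compensation (odd-length linear-phase FIR)."""
    if record.fs < 32.0:
        raise ValueError(f"fs {record.fs} Hz below the 32 Hz minimum")
    taps = _differentiator_taps(record.fs)
    if record.n_samples <= taps.size:
        raise ValueError(f"record ({record.n_samples} samples) shorter than "
                         f"the filter ({taps.size} taps)")
    full = np.convolve(record.samples, taps, mode="full")
    delay = (taps.size - 1) // 2
    y = full[delay:delay + record.n_samples]
    return FilteredPpg(y, record.fs, record.start_time)


def adaptive_threshold_peaks(filtered: FilteredPpg,
                             refractory: float = DEFAULT_REFRACTORY,
                             ) -> np.ndarray:
    """Detect upslope peaks in the filtered signal with a tracking threshold.

    The threshold is 0.5 x an exponentially weighted mean (decay 0.125,
    i.e. roughly the last 8 accepted peaks) of accepted peak heights,
    initialised from the 90th percentile of the first 10 s and
    re-initialised from the trailing 3 s after that long without a
    detection — so detection survives step changes in pulse amplitude.
    Returns peak times in seconds.
    """
    y, fs = filtered.samples, filtered.fs
    if y.size == 0:
        return np.empty(0)
    cand, _ = signal.find_peaks(y)
    cand = cand[y[cand] > 0]
    init_span = min(y.size, int(round(10.0 * fs)))
    ewm = float(np.percentile(y[:init_span], 90)) if init_span else 0.0
    if ewm <= 0:
        pos = y[y > 0]
        ewm = float(np.percentile(pos, 90)) if pos.size else 0.0
    if ewm <= 0:
        return np.empty(0)
    accepted: list[int] = []
    last_t = filtered.start_time
    for p in cand:
        t = filtered.start_time + p / fs
        if accepted and t - (filtered.start_time + accepted[-1] / fs) \
                < refractory:
            continue
        if t - last_t >= SILENCE_REINIT:
            j0 = max(0, p - int(round(SILENCE_REINIT * fs)))
            seg = y[j0:p + 1]
            seg = seg[seg > 0]
            if seg.size:
                ewm = float(np.percentile(seg, 90))
                log.debug("threshold re-initialised at t=%.1f s", t)
        if y[p] >= THRESH_FACTOR * ewm:
            accepted.append(p)
            ewm = (1.0 - THRESH_DECAY) * ewm + THRESH_DECAY * float(y[p])
            last_t = t
    return filtered.start_time + np.asarray(accepted, dtype=float) / fs


def _first_local_max(x: np.ndarray) -> int | None:
    """Index of the first interior local maximum (plateau-aware); None if
    the segment only rises to its end (truncated pulse)."""
    peaks, _ = signal.find_peaks(x)
    if peaks.size:
        return int(peaks[0])
    imax = int(np.argmax(x))
    if imax >= x.size - 1:
        return None
    # plateau maximum: first occurrence of the global max not at the edge
    return imax if imax > 0 else None


def _last_local_min(x: np.ndarray) -> int | None:
    """Index of the last interior local minimum; falls back to the last
    occurrence of the global minimum (flat inter-pulse baseline)."""
    troughs, _ = signal.find_peaks(-x)
    if troughs.size:
        return int(troughs[-1])
    rev = x[::-1]
    imin = x.size - 1 - int(np.argmin(rev))
    if imin >= x.size - 1:
        return None
    return imin


def locate_pulse_extrema(record: WaveformRecord, upslope_times: np.ndarray,
                         search: float = SEARCH_WINDOW) -> PulseFiducials:
    """Anchor each upslope peak to the raw pulse maximum (first local max
    within 400 ms after) and pulse foot (last local min within 400 ms
    before); pulses lacking either landmark are discarded."""
    x, fs = record.samples, record.fs
    w = max(1, int(round(search * fs)))
    ups, feet, maxs, amps, f_idx, m_idx = [], [], [], [], [], []
    for t in np.asarray(upslope_times, dtype=float):
        p = int(round((t - record.start_time) * fs))
        if not 0 <= p < x.size:
            continue
        fwd = x[p:min(x.size, p + w + 1)]
        jmax = _first_local_max(fwd)
        if jmax is None:
            log.debug("pulse at %.2f s discarded: no maximum in window", t)
            continue
        back = x[max(0, p - w):p + 1]
        jmin = _last_local_min(back)
        if jmin is None:
            log.debug("pulse at %.2f s discarded: no foot in window", t)
            continue
        i_max = p + jmax
        i_foot = max(0, p - w) + jmin
        amp = float(x[i_max] - x[i_foot])
        if amp <= 0 or i_foot >= i_max:
            continue
        ups.append(t)
        feet.append(record.start_time + i_foot / fs)
        maxs.append(record.start_time + i_max / fs)
        amps.append(amp)
        f_idx.append(i_foot)
        m_idx.append(i_max)
    return PulseFiducials(np.asarray(ups), np.asarray(feet), np.asarray(maxs),
                          amplitudes=np.asarray(amps),
                          foot_idx=np.asarray(f_idx, int),
                          max_idx=np.asarray(m_idx, int))


def medium_amplitude_point(record: WaveformRecord,
                           fiducials: PulseFiducials) -> np.ndarray:
    """50 %-amplitude crossing time of each pulse upslope.

    The target level is foot value + half the foot-to-peak amplitude; the
    earliest bracketing sample pair on the upslope is linearly interpolated.
    Because the target scales with the pulse, the crossing time is invariant
    to amplitude scaling of the record.
    """
    x, fs = record.samples, record.fs
    out = []
    for i_foot, i_max, amp in zip(fiducials.foot_idx, fiducials.max_idx,
                                  fiducials.amplitudes):
        target = x[i_foot] + 0.5 * amp
        seg = x[i_foot:i_max + 1]
        above = np.nonzero(seg >= target)[0]
        if above.size == 0:  # cannot happen for amp > 0, guard anyway
            out.append(np.nan)
            continue
        j = int(above[0])
        if j == 0:
            t = record.start_time + i_foot / fs
        else:
            y0, y1 = seg[j - 1], seg[j]
            frac = (target - y0) / (y1 - y0) if y1 != y0 else 0.0
            t = record.start_time + (i_foot + j - 1 + frac) / fs
        out.append(t)
    times = np.asarray(out, dtype=float)
    valid = np.isfinite(times)
    return times[valid]


def extract_fiducials(record: WaveformRecord) -> PulseFiducials:
    """Filter -> adaptive peaks -> raw-signal landmarks -> 50 % points."""
    if record.modality != "ppg":
        raise ValueError("extract_fiducials expects a PPG record")
    filtered = lowpass_differentiate(record)
    ups = adaptive_threshold_peaks(filtered)
    fid = locate_pulse_extrema(record, ups)
    fid.map_times = medium_amplitude_point(record, fid)
    return fid


def extract_pulses(record: WaveformRecord) -> BeatSeries:
    """Medium-amplitude-point beat series of a PPG record."""
    fid = extract_fiducials(record)
    t = np.asarray(fid.map_times, dtype=float)
    t = np.unique(t)
    log.info("PPG: %d pulses over %.1f s", t.size, record.duration)
    return BeatSeries(t, "ppg")


def extract_prv(record: WaveformRecord) -> RateSeries:
    """Pulse-rate-variability series: 60/dt between consecutive
    medium-amplitude points, with the same implausible-gap guard as HRV."""
    return beats_to_rate(extract_pulses(record))
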