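"""R-peak detection and HRV extraction from single-channel ECG.

The beat detector is an envelope-flattening variant of Pan-Tompkins: the
signal is segmented into 60 s epochs, notch-filtered at 50 Hz and
mean-removed, then the upper and lower envelopes (sliding window max/min)
are subtracted to give a non-negative "flattened" signal F whose peaks mark
candidate QRS complexes.  Candidates above an adaptive threshold and outside
a 250 ms refractory period are refined to the dominant extremum of the
preprocessed ECG, which makes the detector robust to inverted leads.  The
heart-rate-variability series is the instantaneous rate between consecutive
R-peaks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .types import BeatSeries, RateSeries, WaveformRecord, beats_to_rate

log = logging.getLogger(__name__)

DEFAULT_EPOCH_LENGTH = 60.0      # s
DEFAULT_ENVELOPE_WINDOW = 0.10   # s, QRS-scale
DEFAULT_REFRACTORY = 0.25        # s (240 bpm ceiling)
DEFAULT_REFINE_WINDOW = 0.05     # s, extremum search around F-peak
NOTCH_FREQ = 50.0                # Hz power line
NOTCH_Q = 30.0
MIN_EPOCH_WARN = 10.0            # s


@dataclass
class EcgEpoch:
    """A 60 s (nominal) slice of an ECG record."""

    samples: np.ndarray
    fs: float
    epoch_start: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def epoch_length(self) -> float:
        return self.samples.size / self.fs


@dataclass
class FlattenedEcg:
    """Envelope-difference signal F = U - L with its envelopes."""

    F: np.ndarray
    U: np.ndarray
    L: np.ndarray
    fs: float
    epoch_start: float


def segment_epochs(record: WaveformRecord,
                   epoch_length: float = DEFAULT_EPOCH_LENGTH
                   ) -> list[EcgEpoch]:
    """Split a record into consecutive epochs; the final partial epoch is
    retained (with a warning when shorter than 10 s)."""
    if record.n_samples == 0:
        raise ValueError("cannot segment an empty record")
    n_per = int(round(epoch_length * record.fs))
    epochs = []
    for i0 in range(0, record.n_samples, n_per):
        chunk = record.samples[i0:i0 + n_per]
        ep = EcgEpoch(chunk, record.fs, record.start_time + i0 / record.fs)
        if ep.epoch_length < MIN_EPOCH_WARN:
            log.warning("trailing epoch of %.1f s (< %.0f s) processed "
                        "anyway", ep.epoch_length, MIN_EPOCH_WARN)
        epochs.append(ep)
    return epochs


def preprocess_epoch(epoch: EcgEpoch) -> EcgEpoch:
    """Remove 50 Hz power-line interference (IIR notch, Q = 30, zero phase)
    and the mean."""
    if epoch.fs <= 100.0:
        raise ValueError(f"fs {epoch.fs} Hz too low for 50 Hz notch "
                         "filtering (need > 100 Hz)")
    b, a = signal.iirnotch(NOTCH_FREQ, NOTCH_Q, fs=epoch.fs)
    x = epoch.samples
    padlen = min(3 * max(len(a), len(b)), x.size - 1)
    if x.size > 3:
        x = signal.filtfilt(b, a, x, padlen=padlen)
    x = x - np.mean(x)
    return EcgEpoch(x, epoch.fs, epoch.epoch_start)


def _window_samples(envelope_window: float, fs: float) -> int:
    w = int(round(envelope_window * fs))
    if w % 2 == 0:  # keep the window centred
        w += 1
    return max(w, 3)


def flatten(epoch: EcgEpoch,
            envelope_window: float = DEFAULT_ENVELOPE_WINDOW) -> FlattenedEcg:
    """Compute U (sliding max), L (sliding min) and F = U - L.

    The window is centred and truncated at the epoch edges.
    """
    w = _window_samples(envelope_window, epoch.fs)
    if w < 2 or envelope_window * epoch.fs < 2:
        raise ValueError("envelope window must span at least 2 samples")
    if w > epoch.samples.size:
        raise ValueError(f"envelope window ({w} samples) longer than epoch "
                         f"({epoch.samples.size} samples)")
    # mode='nearest' replicates edge values, which for max/min equals a
    # truncated window
    U = ndimage.maximum_filter1d(epoch.samples, size=w, mode="nearest")
    L = ndimage.minimum_filter1d(epoch.samples, size=w, mode="nearest")
    return FlattenedEcg(U - L, U, L, epoch.fs, epoch.epoch_start)


def detect_r_peaks(flattened: FlattenedEcg, epoch: EcgEpoch,
                   refractory: float = DEFAULT_REFRACTORY,
                   refine_window: float = DEFAULT_REFINE_WINDOW,
                   ) -> BeatSeries:
    """Locate R-peaks from the flattened signal.

    Candidates are local maxima of F above an adaptive threshold
    (0.4 x the epoch's 95th percentile of F, floored at 3 x its median) with
    a 250 ms refractory period, then refined to the extremum of largest
    absolute amplitude of the preprocessed ECG within +/-50 ms.  The
    threshold is relative, so beat times are invariant to amplitude scaling.
    """
    F, fs = flattened.F, flattened.fs
    if F.size == 0:
        return BeatSeries(np.empty(0), "ecg")
    thr = max(0.4 * float(np.percentile(F, 95)), 3.0 * float(np.median(F)))
    dist = max(1, int(round(refractory * fs)))
    peaks, _ = signal.find_peaks(F, height=thr if thr > 0 else None,
                                 distance=dist)
    half = max(1, int(round(refine_window * fs)))
    x = epoch.samples
    times: list[float] = []
    for p in peaks:
        i0, i1 = max(0, p - half), min(x.size, p + half + 1)
        j = i0 + int(np.argmax(np.abs(x[i0:i1])))
        times.append(flattened.epoch_start + j / fs)
    times_arr = np.sort(np.asarray(times))
    # refinement can merge neighbouring candidates; keep the earlier
    keep: list[float] = []
    for t in times_arr:
        if not keep or t - keep[-1] > refractory:
            keep.append(t)
    return BeatSeries(np.asarray(keep), "ecg")


def extract_beats(record: WaveformRecord,
                  epoch_length: float = DEFAULT_EPOCH_LENGTH,
                  envelope_window: float = DEFAULT_ENVELOPE_WINDOW,
                  refractory: float = DEFAULT_REFRACTORY,
                  context_pad: float = 1.0) -> BeatSeries:
    """Epoch-wise R-peak detection stitched across epoch boundaries.

    Each epoch is detected on a slice padded by ``context_pad`` seconds of
    neighbouring signal so beats straddling a boundary are not lost to edge
    truncation; only beats inside the epoch proper are kept, and duplicates
    within the refractory period across boundaries are removed keeping the
    earlier.
    """
    if record.modality != "ecg":
        raise ValueError("extract_beats expects an ECG record")
    epochs = segment_epochs(record, epoch_length)
    fs = record.fs
    n = record.n_samples
    all_times: list[float] = []
    for ep in epochs:
        rel_start = ep.epoch_start - record.start_time
        i0 = max(0, int(round((rel_start - context_pad) * fs)))
        i1 = min(n, int(round((rel_start + ep.epoch_length + context_pad)
                              * fs)))
        padded = EcgEpoch(record.samples[i0:i1], fs,
                          record.start_time + i0 / fs)
        pre = preprocess_epoch(padded)
        flat = flatten(pre, envelope_window)
        beats = detect_r_peaks(flat, pre, refractory)
        lo = ep.epoch_start - 0.5 / fs
        hi = ep.epoch_start + ep.epoch_length - 0.5 / fs
        for t in beats.times:
            if lo <= t < hi:
                all_times.append(t)
    all_times.sort()
    keep: list[float] = []
    for t in all_times:
        if not keep or t - keep[-1] > refractory:
            keep.append(t)
    log.info("ECG: %d beats over %.1f s", len(keep), record.duration)
    return BeatSeries(np.asarray(keep), "ecg")


def extract_hrv(record: WaveformRecord,
                epoch_length: float = DEFAULT_EPOCH_LENGTH,
                envelope_window: float = DEFAULT_ENVELOPE_WINDOW) -> RateSeries:
    """Full chain: segment -> preprocess -> flatten -> detect -> stitch ->
    rate, i.e. the HRV series of a single-channel ECG record."""
    beats = extract_beats(record, epoch_length, envelope_window)
    return beats_to_rate(beats)
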