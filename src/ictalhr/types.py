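"""Shared containers for waveforms, beat fiducials and rate series.

All timestamps are seconds from the record/session start, double precision.
Rates are beats per minute.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: physiological plausibility band for instantaneous heart rate, bpm
HR_MIN = 30.0
HR_MAX = 220.0

#: inter-beat gaps outside this band (seconds) are treated as implausible
GAP_MIN = 60.0 / HR_MAX
GAP_MAX = 60.0 / HR_MIN


@dataclass
class WaveformRecord:
    """Uniformly sampled single-channel physiological signal.

    Parameters
    ----------
    samples : ndarray
        Amplitude values (mV for ECG, arbitrary units for PPG).
    fs : float
        Sampling rate in Hz.
    modality : str
        ``"ecg"`` or ``"ppg"``.
    start_time : float
        Time origin in seconds (0 for synthetic records).
    """

    samples: np.ndarray
    fs: float
    modality: str
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.modality not in ("ecg", "ppg"):
            raise ValueError(f"unknown modality {self.modality!r}")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        """Sample timestamps in seconds (record-relative)."""
        return self.start_time + np.arange(self.n_samples) / self.fs


@dataclass
class BeatSeries:
    """Ordered beat fiducials: R-peaks (ECG) or medium-amplitude points (PPG)."""

    times: np.ndarray
    source_modality: str

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("beat times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass
class RateSeries:
    """Instantaneous heart/pulse rate derived from inter-beat intervals.

    Each rate sample is timestamped at the later beat of its pair and equals
    60 / (inter-beat gap in seconds).  The series is unevenly sampled at the
    native beat times; downstream windows are therefore time-based.
    """

    times: np.ndarray
    rates: np.ndarray
    source_modality: str = "ecg"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.times.shape != self.rates.shape:
            raise ValueError("times and rates must have equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("rate timestamps must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)


def beats_to_rate(beats: BeatSeries, *, gap_min: float = GAP_MIN,
                  gap_max: float = GAP_MAX) -> RateSeries:
    """Convert a beat series to an instantaneous rate series.

    One rate sample is emitted per consecutive beat pair; pairs whose gap
    falls outside ``[gap_min, gap_max]`` seconds (30-220 bpm by default) are
    dropped as implausible — dropouts and artifact-bridging gaps produce no
    rate sample rather than a spurious one.
    """
    import logging

    log = logging.getLogger(__name__)
    if len(beats) < 2:
        log.warning("fewer than 2 beats (%d): empty rate series", len(beats))
        return RateSeries(np.empty(0), np.empty(0), beats.source_modality)
    gaps = np.diff(beats.times)
    ok = (gaps >= gap_min) & (gaps <= gap_max)
    n_dropped = int(np.sum(~ok))
    if n_dropped:
        log.debug("dropped %d implausible inter-beat gaps", n_dropped)
    return RateSeries(beats.times[1:][ok], 60.0 / gaps[ok],
                      beats.source_modality)
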