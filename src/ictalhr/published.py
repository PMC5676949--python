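"""Published per-patient results of the 11-patient hospital study.

The detector this package implements was originally evaluated on a
non-public clinical dataset: 11 refractory (fronto-)temporal-lobe-epilepsy
patients monitored for 701 h in total with simultaneous hospital ECG,
wearable ECG and wrist PPG, capturing 47 seizures.  The raw recordings are
not available, but the printed per-patient tables are, and every published
aggregate is an arithmetic function of them.  These constants are inputs to
the consistency checks in the test suite and acceptance script; aggregates
are always recomputed from them at run time.
"""

from __future__ import annotations

MODALITIES = ("hospital_ecg", "wearable_ecg", "wearable_ppg")

#: cohort summary: patient id -> (n seizures, recording duration in hours)
COHORT = {
    "1": (6, 20.0),
    "2": (3, 72.0),
    "3": (1, 72.0),
    "4": (7, 73.0),
    "5": (8, 95.0),
    "6": (2, 23.0),
    "7": (1, 43.0),
    "8": (10, 71.0),
    "9": (2, 91.0),
    "10": (5, 71.0),
    "11": (2, 70.0),
}

#: per-patient printed performance: patient id -> (Se %, FP/h, PPV %)
PER_PATIENT = {
    "hospital_ecg": {
        "1": (33, 3.98, 2.50), "2": (0, 1.55, 0.00), "3": (100, 1.55, 0.89),
        "4": (71, 2.27, 2.94), "5": (88, 2.30, 3.10), "6": (50, 2.91, 1.02),
        "7": (100, 0.45, 5.00), "8": (50, 3.44, 2.02), "9": (0, 0.40, 0.00),
        "10": (80, 1.03, 6.56), "11": (50, 2.73, 0.34),
    },
    "wearable_ecg": {
        "1": (33, 3.98, 2.44), "2": (33, 2.06, 0.67), "3": (100, 2.09, 0.65),
        "4": (100, 2.89, 3.23), "5": (88, 1.96, 3.61), "6": (50, 4.24, 0.99),
        "7": (100, 1.03, 2.22), "8": (90, 2.64, 4.62), "9": (0, 0.62, 0.00),
        "10": (75, 1.53, 3.54), "11": (50, 2.78, 0.36),
    },
    "wearable_ppg": {
        "1": (33, 1.77, 5.26), "2": (33, 1.49, 0.92), "3": (0, 2.27, 0.00),
        "4": (43, 1.91, 2.11), "5": (38, 1.55, 1.99), "6": (100, 2.41, 3.39),
        "7": (0, 1.64, 0.00), "8": (20, 2.53, 1.09), "9": (0, 1.08, 0.00),
        "10": (0, 2.06, 0.00), "11": (100, 1.94, 1.04),
    },
}

#: missed seizures per modality (of the 47 total)
MISSED = {"hospital_ecg": 20, "wearable_ecg": 14, "wearable_ppg": 32}

#: seizures undetectable for physiological reasons: HR decrease (5),
#: no HR change (3), small (< 20 bpm) HR increase (3)
PHYSIO_UNDETECTABLE = 11

#: PPG seizures missed because motion artifacts destroyed the pulse signal
PPG_MOTION_MISSED = 26

#: seizure counts per duration bin (0-20, 20-40, 40-60, > 60 s), known
#: durations only
DURATION_BIN_COUNTS = (9, 9, 3, 10)


def total_seizures() -> int:
    return sum(n for n, _ in COHORT.values())


def total_hours() -> float:
    return sum(h for _, h in COHORT.values())
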