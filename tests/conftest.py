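import numpy as np
import pytest

import ictalhr as ih


@pytest.fixture(scope="session")
def model():
    """Substitute SVM trained on the seeded synthetic cohort (the clinical
    training data is not public); shared across tests."""
    return ih.train_default_model(seed=12345)


@pytest.fixture(scope="session")
def clean_record():
    """One clean 600 s paired recording with a +30 bpm ictal ramp."""
    cfg = ih.SimConfig(
        duration=600.0, baseline_hr=70.0, hr_jitter_sd=2.0,
        seizures=(ih.SimSeizureEvent(onset=300.0, duration=60.0,
                                     delta_hr=30.0, ramp_time=30.0),),
        seed=3)
    ecg, ppg, truth = ih.generate_record(cfg)
    return cfg, ecg, ppg, truth


@pytest.fixture(scope="session")
def cohort20():
    """20 seeded records, one +30 bpm seizure each, no artifacts."""
    return ih.generate_cohort(20, seed=7)


@pytest.fixture(scope="session")
def cohort20_motion():
    """Same cohort shape with motion bursts covering the PPG seizure
    windows only."""
    return ih.generate_cohort(20, seed=7, ppg_motion_on_seizures=True)


def recovery_fraction(truth_times: np.ndarray, found_times: np.ndarray,
                      tol: float) -> float:
    """Fraction of ground-truth fiducials with a detection within tol s."""
    if truth_times.size == 0:
        return 1.0
    if found_times.size == 0:
        return 0.0
    d = np.abs(truth_times[:, None] - found_times[None, :]).min(axis=1)
    return float(np.mean(d <= tol))
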