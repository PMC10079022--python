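import numpy as np
import pytest

import arousalhrv as ah


@pytest.fixture(scope="session")
def clean_recording():
    """Zero-noise recording exercising every etiology plus decoys/reclassification."""
    sc = ah.Scenario(seed=7, prob_noise_sd=0.0, decoy_rate=0.5,
                     uod_reclassifiable_fraction=0.5)
    return ah.generate_recording(sc)


@pytest.fixture(scope="session")
def noisy_recording():
    """Default-noise recording, ECG included, for detector-level tests."""
    sc = ah.Scenario(seed=9, duration_s=600.0,
                     n_arousals_by_etiology={"Spontaneous": 5})
    return ah.generate_recording(sc, with_ecg=True, fs=256.0, ecg_noise_sd=0.1)


@pytest.fixture(scope="session")
def surge_cohort_analysis():
    """Pooled analysis of a 300+ arousal cohort with the default 8 bpm surge."""
    cohort = ah.generate_cohort(ah.Scenario(seed=0), 14, seed=11)
    analyses = [
        ah.analyze_recording(r.prob, r.events, r.hypnogram,
                             peak_times_s=r.truth.r_peak_times_s,
                             duration_s=r.scenario.duration_s, gender=r.gender)
        for r in cohort
    ]
    return ah.analyze_cohort(analyses)


def rng(seed=0):
    return np.random.default_rng(seed)
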