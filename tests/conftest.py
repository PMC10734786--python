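from dataclasses import replace

import numpy as np
import pytest

import pwvalid as pv


@pytest.fixture(scope="session")
def figure_model():
    """The worked grading example: mean 0.36 m/s, SD 0.44 m/s."""
    return pv.DifferenceModel(0.36, 0.44)


@pytest.fixture(scope="session")
def quota_cohort():
    """Canonical 85-participant cohort satisfying every composition quota."""
    return pv.quota_satisfying_cohort(pv.SimulationConfig(n_participants=85))


@pytest.fixture(scope="session")
def quota_study(quota_cohort):
    """Quota cohort plus low-noise sessions; the canonical passing fixture."""
    cfg = pv.SimulationConfig(n_participants=85, bias_constant=0.2,
                              bias_between_sd=0.15, test_noise_sd=0.1,
                              reference_noise_sd=0.1, seed=7)
    sessions = pv.simulate_sessions(quota_cohort, cfg)
    records = [replace(r, reference_pwv=float(
        np.mean([x.pwv for x in s.reference_readings])))
        for r, s in zip(quota_cohort, sessions)]
    return records, sessions


@pytest.fixture(scope="session")
def full_config():
    """A validation config with every reporting element declared."""
    return pv.ValidationConfig(
        quality_criteria={"stability_threshold": 0.05},
        n_enrolled=90, software_version="1.0.0", hardware_version="revA",
        measurement_principle="applanation tonometry, transit-time PWV",
        fiducial_point="diastolic foot",
        detection_method="intersecting tangent at 1 ms resolution",
        data_availability="raw data deposited in a public repository",
        training_validation_separate=True)


@pytest.fixture(scope="session")
def synthetic_beat_1khz():
    """Noiseless 12-beat waveform at 1 kHz with exact ground-truth feet."""
    return pv.synthesize_waveform(60, 12, sampling_rate=1000, seed=0)
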