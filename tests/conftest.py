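import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cardioresp import ModulationSpec, generate_ecg, generate_ppg, generate_record

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def clean_ecg_record():
    """60 s clean ECG at 60 bpm: no modulation, no noise."""
    spec = ModulationSpec(duration_s=60, fs=300, hr_bpm=60, rr_bpm=15,
                          am_depth=0.0, bw_amp=0.0, fm_depth=0.0,
                          noise_sd=0.0, seed=1)
    return generate_ecg(spec)


@pytest.fixture(scope="session")
def modulated_ecg_record():
    """120 s ECG with the study-like modulation depths and light noise."""
    spec = ModulationSpec(duration_s=120, fs=300, hr_bpm=70, rr_bpm=15,
                          am_depth=0.2, bw_amp=0.1, fm_depth=0.1,
                          noise_sd=0.02, seed=2)
    return generate_ecg(spec)


@pytest.fixture(scope="session")
def clean_ppg_record():
    """60 s clean PPG at 75 bpm."""
    spec = ModulationSpec(duration_s=60, fs=300, hr_bpm=75, rr_bpm=15,
                          am_depth=0.0, bw_amp=0.0, fm_depth=0.0,
                          noise_sd=0.0, seed=3)
    return generate_ppg(spec)


@pytest.fixture(scope="session")
def modulated_ppg_record():
    spec = ModulationSpec(duration_s=120, fs=300, hr_bpm=70, rr_bpm=15,
                          am_depth=0.2, bw_amp=0.1, fm_depth=0.1,
                          noise_sd=0.01, seed=4)
    return generate_ppg(spec)
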