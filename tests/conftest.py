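import numpy as np
import pytest

from ecgkit.synthetic_ecg import NoiseSpec, SimulationConfig, add_noise, generate_clean_ecg


@pytest.fixture(scope="session")
def clean_record_60s():
    """One minute of clean synthetic ECG at the default 72 bpm."""
    return generate_clean_ecg(SimulationConfig(duration=60.0, seed=123))


@pytest.fixture(scope="session")
def noisy_pair_10s():
    """(clean, noisy) 10-second signals at 10 dB SNR, fixed seed."""
    record = generate_clean_ecg(SimulationConfig(duration=10.0, seed=42))
    clean = record.channel()
    noisy = add_noise(clean, NoiseSpec(snr_db=10.0, seed=43))
    return clean, noisy


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
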