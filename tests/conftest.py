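import numpy as np
import pytest

from calmflow import SimulationConfig, generate_eeg_recording, rereference


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def small_config():
    """A small, fast cohort: 3 participants, 10-s sessions."""
    return SimulationConfig(n_participants=3, session_length=10.0,
                            env_n_samples=200, seed=11)


@pytest.fixture
def clean_tone_config():
    """Noise-free generator with exact session lengths: pure carriers only."""
    return SimulationConfig(
        n_participants=2, session_length=12.0, session_jitter=0.0,
        noise_sigma_uV=0.0, participant_amp_sigma=0.0,
        session_amp_sigma_uV=0.0, ttl_interval_sigma=0.0, seed=5)


@pytest.fixture
def rereferenced_recording(small_config):
    return rereference(generate_eeg_recording(1, "AC", small_config))
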