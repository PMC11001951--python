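import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")

from dyadgaze import synthetic as syn


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def preset():
    return syn.study_preset()


@pytest.fixture(scope="session")
def small_stream_config():
    """Scaled-down stream: 4 rounds of 10 s, no calibration; keeps the
    session structure while making per-test simulation cheap."""
    return syn.StreamConfig(round_length_s=10.0, inter_round_gap_s=1.0,
                            include_calibration=False)


@pytest.fixture(scope="session")
def clean_stream_config():
    """Zero-noise, zero-missingness, exact-count labels: the round-trip
    configuration in which the pipeline must recover generative fractions
    up to frame quantisation."""
    return syn.StreamConfig(round_length_s=10.0, inter_round_gap_s=1.0,
                            include_calibration=False, noise_sd_cm=0.0,
                            missing_rate=0.0, timestamp_jitter_sd_s=0.0,
                            exact_fractions=True)


@pytest.fixture(scope="session")
def participant_meta():
    from dyadgaze.session_io import ParticipantMeta
    return ParticipantMeta(id="P001", age=28.0, sex=0, aq=19.5,
                           discomfort=False)


@pytest.fixture(scope="session")
def small_session(participant_meta, preset, small_stream_config):
    return syn.generate_session(participant_meta, preset.effects,
                                small_stream_config, seed=7)
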