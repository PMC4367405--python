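import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from kneerehab import PipelineConfig, preprocess_session
from kneerehab.evaluation import build_records
from kneerehab.signal_io import SITES, Session, SensorStream
from kneerehab.synth import SimParams, simulate_subject

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


def make_static_session(
    n: int = 400,
    rate: float = 40.0,
    gravity_vec=(0.0, 1.0, 0.0),
    noise_sigma: float = 0.0,
    seed: int = 0,
    with_gyro: bool = True,
) -> Session:
    """A motionless session: constant gravity projection plus optional noise."""
    rng = np.random.default_rng(seed)
    streams = {}
    for site in SITES:
        accel = np.tile(np.asarray(gravity_vec, dtype=float), (n, 1))
        if noise_sigma > 0:
            accel = accel + rng.normal(0.0, noise_sigma, accel.shape)
        gyro = np.zeros((n, 3)) if with_gyro else None
        streams[site] = SensorStream(site=site, accel=accel, gyro=gyro, sampling_rate=rate)
    return Session(streams=streams, subject_id="static")


@pytest.fixture()
def static_session() -> Session:
    return make_static_session()


@pytest.fixture(scope="session")
def noisefree_subject_sessions():
    """Full protocol for one subject with every stochastic magnitude zeroed."""
    return simulate_subject(params=SimParams().noise_free(), seed=1)


@pytest.fixture(scope="session")
def small_corpus_sessions():
    """Two-subject corpus at default noise (for evaluation-level tests)."""
    from kneerehab.synth import simulate_corpus

    return simulate_corpus(n_subjects=2, seed=7)


@pytest.fixture(scope="session")
def small_corpus_records(small_corpus_sessions, config):
    return build_records(small_corpus_sessions, config)


@pytest.fixture(scope="session")
def noisefree_slr_prepped(config):
    """Preprocessed noise-free standard SLR session (10 reps at 45 degrees)."""
    sessions = simulate_subject(params=SimParams().noise_free(), seed=3)
    slr = next(s for s in sessions if s.true_exercise == "SLR" and s.variant == "normal")
    return slr, preprocess_session(slr, config.filters)
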