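"""Shared fixtures: tiny synthetic cohorts and a cache of trained studies."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from insolenet.channels import N_CHANNELS, PhysioStream, SensorRecording
from insolenet.model import DenseNetConfig
from insolenet.preprocessing import apply_standardizer, extract_windows, fit_standardizer
from insolenet.simulate import CohortConfig, ProtocolConfig, simulate_cohort

settings.register_profile(
    "default", derandomize=True, max_examples=40, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


#: A deliberately tiny feature extractor for fast unit tests (T(67) = 3).
TINY_DENSENET = DenseNetConfig(
    initial_channels=8, growth_rate=4, layers_per_block=1, n_blocks=2,
    stem_kernel=7, stem_stride=4, pool_stride=2,
)


def make_recording(subject_id="S01", n=700, fs=33.3, seed=0) -> SensorRecording:
    rng = np.random.default_rng(seed)
    return SensorRecording(subject_id, fs, rng.normal(size=(n, N_CHANNELS)))


def make_stream(subject_id="S01", duration=30.0, seed=0) -> PhysioStream:
    rng = np.random.default_rng(seed)
    t = np.cumsum(rng.uniform(2, 5, size=int(duration)))
    t = np.concatenate([[0.0], t[t < duration]])
    return PhysioStream(
        subject_id,
        t,
        90 + 30 * t / duration + rng.normal(0, 1, len(t)),
        2 + 5 * t / duration,
    )


@pytest.fixture
def recording() -> SensorRecording:
    return make_recording()


@pytest.fixture
def stream() -> PhysioStream:
    return make_stream()


@pytest.fixture(scope="session")
def tiny_cohort():
    """3 subjects x 90 s at a reduced rate; enough for pipeline plumbing tests."""
    cfg = CohortConfig(
        n_subjects=3,
        protocol=ProtocolConfig(start_speed=3, end_speed=5, stage_seconds=30),
        fs=33.3,
        seed=7,
    )
    return cfg, simulate_cohort(cfg)


@pytest.fixture(scope="session")
def tiny_windows(tiny_cohort):
    """Standardized 2-s windows from the tiny cohort (short: fast training)."""
    _, cohort = tiny_cohort
    recs = [r for r, _ in cohort]
    stats = fit_standardizer(recs)
    windows = []
    for rec, stream in cohort:
        windows.extend(
            extract_windows(apply_standardizer(rec, stats), stream,
                            window_s=2.0, hop_s=1.0)
        )
    return windows


@pytest.fixture(scope="session")
def small_study_cache():
    """Memoized desk-scale LOSO studies keyed by (seed, attention, target).

    Several end-to-end checks share seeds; each study is trained once per
    test session.
    """
    from insolenet.experiments import run_small_study

    cache: dict = {}

    def get(seed: int, attention: bool = True, target: str = "ee"):
        key = (seed, attention, target)
        if key not in cache:
            cache[key] = run_small_study(
                seed, target=target, attention_enabled=attention
            )
        return cache[key]

    return get
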