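"""Shared fixtures: one full synthetic assessment reused across the suite."""

from __future__ import annotations

import time

import numpy as np
import pytest

from gaitreliab import (RunConfig, orient, preprocess, run_assessment,
                        detect_gait_events, estimate_stride_prior)
from gaitreliab.io_preprocess import SubjectMeta
from gaitreliab.synthetic_gait import WalkSpec, generate_walk


@pytest.fixture(scope="session")
def default_spec() -> WalkSpec:
    """Two-minute walk, 1.2-s strides, 1.3-m stride length, 1.80-m subject."""
    return WalkSpec(rng_seed=1,
                    subject_meta=SubjectMeta(subject_id="fixture",
                                             height_m=1.80,
                                             paretic_side="right"))


@pytest.fixture(scope="session")
def default_walk(default_spec):
    return generate_walk(default_spec)


@pytest.fixture(scope="session")
def preprocessed(default_walk):
    recording, _ = default_walk
    return preprocess(recording)


@pytest.fixture(scope="session")
def oriented(preprocessed):
    return {
        placement: orient(stream.accel, stream.gyro,
                          preprocessed.sample_rate_hz, source=placement,
                          walk_span=preprocessed.walk_bounds_per_sensor[placement])
        for placement, stream in preprocessed.sensors.items()
    }


@pytest.fixture(scope="session")
def foot_events(preprocessed, oriented):
    events = {}
    for placement in ("left_foot", "right_foot"):
        span = preprocessed.walk_bounds_per_sensor[placement]
        prior = estimate_stride_prior(
            oriented[placement].accel_ml[span[0]:span[1]],
            preprocessed.sample_rate_hz)
        events[placement] = detect_gait_events(
            oriented[placement], preprocessed.sample_rate_hz,
            foot=placement.split("_")[0], walk_bounds=span, prior=prior)
    return events


@pytest.fixture(scope="session")
def pipeline_result(default_walk):
    """Full pipeline on the fixture walk, with its wall-clock runtime."""
    recording, _ = default_walk
    t0 = time.perf_counter()
    result = run_assessment(recording)
    result.runtime_s = time.perf_counter() - t0
    return result


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture()
def config() -> RunConfig:
    return RunConfig()
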