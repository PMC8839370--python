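"""End-to-end assessment pipeline: recording -> 166-feature vector.

Chain: read/accept a raw recording, preprocess (resample, bias-correct,
trim, walk bounds), validate length, orient every sensor, estimate the
stride prior per foot, detect foot and low-back events, reconstruct stride
displacements via ZUPT, and compute and assemble the feature catalogue.
Every exclusion or repair decision is collected in a run log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Union

from .config import RunConfig
from .errors import (DetectionError, GaitError, LowBackDetectionError,
                     PriorEstimationError)
from .features import (FeatureVector, assemble, asymmetry_features,
                       build_catalogue, complexity_features,
                       frequency_features, spatio_temporal_features)
from .io_preprocess import (GyroBias, LengthVerdict, PreprocessedRecording,
                            RawRecording, preprocess, read_recording,
                            validate_length)
from .lowback_events import LowBackEvents, detect_lowback_events
from .orientation import (OrientedSignal, StrideDisplacement, orient,
                          zupt_stride_displacement)
from .stride_detection import (GaitEvents, StridePrior, detect_gait_events,
                               estimate_stride_prior)

log = logging.getLogger(__name__)


@dataclass
class AssessmentResult:
    assessment_id: str
    excluded: bool
    verdict: Optional[LengthVerdict]
    features: Optional[FeatureVector]
    events: Dict[str, Optional[GaitEvents]] = field(default_factory=dict)
    lowback: Optional[LowBackEvents] = None
    preprocessed: Optional[PreprocessedRecording] = None
    oriented: Dict[str, OrientedSignal] = field(default_factory=dict)
    displacements: Dict[str, Optional[StrideDisplacement]] = field(
        default_factory=dict)
    run_log: List[str] = field(default_factory=list)


def run_assessment(recording: Union[RawRecording, str, Path],
                   bias: Optional[GyroBias] = None,
                   config: Optional[RunConfig] = None,
                   assessment_id: Optional[str] = None) -> AssessmentResult:
    """Run the full pipeline on one assessment.

    A recording failing the ten-second length rule is returned excluded,
    with the verdict and no features; detection failures of individual
    sensors degrade to missing features rather than aborting the run.
    """
    cfg = config or RunConfig()
    run_log: List[str] = []
    if not isinstance(recording, RawRecording):
        recording = read_recording(recording)
    aid = assessment_id or (f"{recording.meta.subject_id}"
                            f"_s{recording.meta.session_id}")

    pre = preprocess(recording, bias, cfg)
    verdict = validate_length(pre, tolerance_s=cfg.length_tolerance_s)
    if not verdict.passed:
        run_log.append(
            "excluded: residual walking length deviates more than "
            f"{cfg.length_tolerance_s} s from the expected "
            f"{verdict.expected_duration_s} s "
            f"(deviations {({k: round(v, 1) for k, v in verdict.deviations_s.items()})})")
        return AssessmentResult(assessment_id=aid, excluded=True,
                                verdict=verdict, features=None,
                                preprocessed=pre, run_log=run_log)

    oriented: Dict[str, OrientedSignal] = {}
    for placement in ("left_foot", "right_foot", "low_back"):
        stream = pre.sensors[placement]
        oriented[placement] = orient(
            stream.accel, stream.gyro, pre.sample_rate_hz, cfg,
            source=placement,
            walk_span=pre.walk_bounds_per_sensor[placement])

    events: Dict[str, Optional[GaitEvents]] = {}
    priors: Dict[str, StridePrior] = {}
    for placement in ("left_foot", "right_foot"):
        foot = placement.split("_")[0]
        span = pre.walk_bounds_per_sensor[placement]
        try:
            prior = estimate_stride_prior(
                oriented[placement].accel_ml[span[0]:span[1]],
                pre.sample_rate_hz, cfg)
            priors[placement] = prior
            events[placement] = detect_gait_events(
                oriented[placement], pre.sample_rate_hz, foot=foot,
                walk_bounds=span, config=cfg, prior=prior)
            rl = events[placement].repair_log
            run_log.append(
                f"{placement}: {events[placement].n_strides} strides, "
                f"{rl.false_negative_insertions} false-negative insertions, "
                f"{rl.false_positive_removals} false-positive removals")
        except (PriorEstimationError, DetectionError) as exc:
            events[placement] = None
            run_log.append(f"{placement}: detection failed: {exc}")

    lowback: Optional[LowBackEvents] = None
    if events["left_foot"] is not None and events["right_foot"] is not None:
        mean_stride = 0.5 * sum(p.average_stride_time_s for p in priors.values())
        lb_prior = StridePrior(average_stride_time_s=mean_stride,
                               dominant_frequency_hz=1.0 / mean_stride)
        try:
            lowback = detect_lowback_events(
                oriented["low_back"], events["left_foot"],
                events["right_foot"], lb_prior,
                walk_bounds=pre.walk_bounds_per_sensor["low_back"], config=cfg)
            for msg in lowback.missing_log:
                run_log.append(f"low_back: {msg}")
        except (LowBackDetectionError, GaitError) as exc:
            run_log.append(f"low_back: detection failed: {exc}")
    else:
        run_log.append("low_back: skipped (foot template unavailable)")

    displacements: Dict[str, Optional[StrideDisplacement]] = {}
    for placement in ("left_foot", "right_foot"):
        ev = events[placement]
        if ev is not None and len(ev.stance_intervals) >= 2:
            displacements[placement] = zupt_stride_displacement(
                oriented[placement], ev.stance_intervals)
        else:
            displacements[placement] = None

    meta = recording.meta
    st = spatio_temporal_features(events["left_foot"], events["right_foot"],
                                  lowback, displacements, meta, cfg)
    stride_freq = None
    if priors:
        stride_freq = 1.0 / (sum(p.average_stride_time_s
                                 for p in priors.values()) / len(priors))
    fr = frequency_features(oriented, walk_bounds=pre.walk_bounds, config=cfg,
                            stride_freq_hz=stride_freq)
    cx = complexity_features(oriented, events["left_foot"],
                             events["right_foot"], cfg)
    asym = asymmetry_features(events["left_foot"], events["right_foot"],
                              displacements, meta, cfg)
    strides_used = {p: (events[p].n_strides if events[p] is not None else 0)
                    for p in ("left_foot", "right_foot")}
    strides_used["low_back"] = (len(lowback.merged_contacts()) - 1
                                if lowback is not None else 0)
    vector = assemble([st, fr, cx, asym], build_catalogue(),
                      assessment_id=aid, strides_used=strides_used)
    for name, reason in sorted(vector.missing.items()):
        run_log.append(f"feature missing: {name} ({reason})")
    return AssessmentResult(assessment_id=aid, excluded=False, verdict=verdict,
                            features=vector, events=events, lowback=lowback,
                            preprocessed=pre, oriented=oriented,
                            displacements=displacements, run_log=run_log)
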