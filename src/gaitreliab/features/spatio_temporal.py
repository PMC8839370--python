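"""Spatio-temporal gait features, summarised as the mean outcome per
10-stride block (partial final blocks are dropped and logged).

Per foot: stride/stance/swing/step time, stride length and velocity (each as
mean, SD and CV of 10-stride blocks), cadence, and height-normalised length
and velocity. From the low back: stride and step timing. Combined: gait
speed, bilateral means and double-support time.
"""

from __future__ import annotations

import logging
from typing import Dict, Optional, Tuple

import numpy as np

from ..config import RunConfig
from ..io_preprocess import SubjectMeta
from ..lowback_events import LowBackEvents
from ..orientation import StrideDisplacement
from ..stride_detection import GaitEvents

log = logging.getLogger(__name__)

Values = Dict[str, float]
Missing = Dict[str, str]

FOOT_BASES = ("stride_time", "stance_time", "swing_time", "step_time",
              "stride_length", "stride_velocity")


def block_stats(series: np.ndarray, block: int) -> Optional[Tuple[float, float, float]]:
    """(mean, sd, cv%) as means of per-block statistics; None if < one block."""
    series = np.asarray(series, dtype=float)
    n_blocks = series.size // block
    if n_blocks == 0:
        return None
    unused = series.size - n_blocks * block
    if unused:
        log.info("block summarisation: %d trailing strides unused "
                 "(block size %d)", unused, block)
    blocks = series[:n_blocks * block].reshape(n_blocks, block)
    means = blocks.mean(axis=1)
    sds = blocks.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cvs = np.where(np.abs(means) > 0, 100.0 * sds / np.abs(means), np.nan)
    return float(means.mean()), float(sds.mean()), float(np.nanmean(cvs))


def _step_times(own: np.ndarray, other: np.ndarray, fs: float) -> np.ndarray:
    """Per-contact step time: preceding contralateral contact -> own contact."""
    out = []
    for c in own:
        prev = other[other < c]
        if prev.size:
            out.append((c - prev[-1]) / fs)
    return np.asarray(out)


def foot_series(events: GaitEvents, other: Optional[GaitEvents],
                lengths: Optional[np.ndarray]) -> Dict[str, np.ndarray]:
    fs = events.sample_rate_hz
    stride = events.stride_times()
    series = {
        "stride_time": stride,
        "stance_time": events.stance_durations(),
        "swing_time": events.swing_durations(),
    }
    if other is not None:
        series["step_time"] = _step_times(events.contact_samples,
                                          other.contact_samples, fs)
    if lengths is not None and lengths.size:
        n = min(lengths.size, stride.size)
        series["stride_length"] = lengths[:n]
        series["stride_velocity"] = lengths[:n] / stride[:n]
    return series


def _emit_block(values: Values, missing: Missing, prefix: str,
                series: Optional[np.ndarray], block: int, reason: str) -> None:
    stats = None if series is None else block_stats(series, block)
    for stat in ("mean", "sd", "cv"):
        name = f"{prefix}_{stat}"
        if stats is None:
            missing[name] = reason
        else:
            values[name] = dict(zip(("mean", "sd", "cv"), stats))[stat]


def spatio_temporal_features(
        events_left: Optional[GaitEvents], events_right: Optional[GaitEvents],
        lowback: Optional[LowBackEvents],
        displacements: Dict[str, Optional[StrideDisplacement]],
        meta: SubjectMeta,
        config: Optional[RunConfig] = None) -> Tuple[Values, Missing]:
    """All 56 spatio-temporal features (feet, low back, combined)."""
    cfg = config or RunConfig()
    block = cfg.block_strides
    values: Values = {}
    missing: Missing = {}
    events = {"left_foot": events_left, "right_foot": events_right}

    for foot in ("left_foot", "right_foot"):
        ev = events[foot]
        other = events["right_foot" if foot == "left_foot" else "left_foot"]
        extras = (f"{foot}_cadence", f"{foot}_stride_length_height_norm",
                  f"{foot}_stride_velocity_height_norm")
        if ev is None:
            for base in FOOT_BASES:
                _emit_block(values, missing, f"{foot}_{base}", None, block,
                            "detection_failed")
            for name in extras:
                missing[name] = "detection_failed"
            continue
        disp = displacements.get(foot)
        lengths = disp.lengths if disp is not None else None
        series = foot_series(ev, other, lengths)
        for base in FOOT_BASES:
            reason = ("insufficient_strides" if base in series
                      else "missing_input")
            _emit_block(values, missing, f"{foot}_{base}",
                        series.get(base), block, reason)
        mean_key = f"{foot}_stride_time_mean"
        if mean_key in values and values[mean_key] > 0:
            values[f"{foot}_cadence"] = 120.0 / values[mean_key]
        else:
            missing[f"{foot}_cadence"] = "insufficient_strides"
        for base, target in (("stride_length", "stride_length_height_norm"),
                             ("stride_velocity", "stride_velocity_height_norm")):
            src = f"{foot}_{base}_mean"
            if src in values:
                values[f"{foot}_{target}"] = values[src] / meta.height_m
            else:
                missing[f"{foot}_{target}"] = missing.get(src, "missing_input")
    _lowback_block(values, missing, lowback, block)
    _combined_block(values, missing, events_left, events_right,
                    displacements, meta, block)
    return values, missing


def _lowback_block(values: Values, missing: Missing,
                   lowback: Optional[LowBackEvents], block: int) -> None:
    src = "low_back"
    names = ([f"{src}_{b}_{s}" for b in ("stride_time", "step_time")
              for s in ("mean", "sd", "cv")]
             + [f"{src}_cadence", f"{src}_stride_time_range"])
    if lowback is None:
        for name in names:
            missing[name] = "lowback_detection_failed"
        return
    fs = lowback.sample_rate_hz
    # stride times per matched foot, interleaved in contact order
    tagged = []
    for foot, contacts in lowback.contact_samples.items():
        for start, nxt in zip(contacts[:-1], contacts[1:]):
            tagged.append((start, (nxt - start) / fs))
    stride = np.array([d for _, d in sorted(tagged)])
    step = np.diff(lowback.merged_contacts()) / fs
    _emit_block(values, missing, f"{src}_stride_time", stride, block,
                "insufficient_strides")
    _emit_block(values, missing, f"{src}_step_time", step, block,
                "insufficient_strides")
    if f"{src}_stride_time_mean" in values and values[f"{src}_stride_time_mean"] > 0:
        values[f"{src}_cadence"] = 120.0 / values[f"{src}_stride_time_mean"]
    else:
        missing[f"{src}_cadence"] = "insufficient_strides"
    if stride.size:
        values[f"{src}_stride_time_range"] = float(stride.max() - stride.min())
    else:
        missing[f"{src}_stride_time_range"] = "insufficient_strides"


def _double_support(events_left: GaitEvents, events_right: GaitEvents
                    ) -> np.ndarray:
    """Per-left-stride total double-support time (both feet in stance)."""
    fs = events_left.sample_rate_hz
    n = int(max(events_left.contact_samples[-1],
                events_right.contact_samples[-1])) + 1
    mask = np.zeros(n, dtype=bool)
    other = np.zeros(n, dtype=bool)
    for s, e in events_left.stance_intervals:
        mask[s:e] = True
    for s, e in events_right.stance_intervals:
        other[s:e] = True
    both = mask & other
    out = []
    for c0, c1 in zip(events_left.contact_samples[:-1],
                      events_left.contact_samples[1:]):
        out.append(both[c0:c1].sum() / fs)
    return np.asarray(out)


def _combined_block(values: Values, missing: Missing,
                    events_left: Optional[GaitEvents],
                    events_right: Optional[GaitEvents],
                    displacements: Dict[str, Optional[StrideDisplacement]],
                    meta: SubjectMeta, block: int) -> None:
    src = "combined"
    if events_left is None or events_right is None:
        for name in (f"{src}_gait_speed", f"{src}_gait_speed_height_norm",
                     f"{src}_stride_time_bilateral_mean",
                     f"{src}_stride_length_bilateral_mean",
                     f"{src}_stride_length_bilateral_height_norm",
                     f"{src}_double_support_time_mean"):
            missing[name] = "detection_failed"
        return

    def _pick(name: str) -> Optional[float]:
        l, r = values.get(f"left_foot_{name}"), values.get(f"right_foot_{name}")
        if l is None or r is None:
            return None
        return 0.5 * (l + r)

    speed = _pick("stride_velocity_mean")
    if speed is not None:
        values[f"{src}_gait_speed"] = speed
        values[f"{src}_gait_speed_height_norm"] = speed / meta.height_m
    else:
        missing[f"{src}_gait_speed"] = "missing_input"
        missing[f"{src}_gait_speed_height_norm"] = "missing_input"
    stride_t = _pick("stride_time_mean")
    if stride_t is not None:
        values[f"{src}_stride_time_bilateral_mean"] = stride_t
    else:
        missing[f"{src}_stride_time_bilateral_mean"] = "missing_input"
    length = _pick("stride_length_mean")
    if length is not None:
        values[f"{src}_stride_length_bilateral_mean"] = length
        values[f"{src}_stride_length_bilateral_height_norm"] = length / meta.height_m
    else:
        missing[f"{src}_stride_length_bilateral_mean"] = "missing_input"
        missing[f"{src}_stride_length_bilateral_height_norm"] = "missing_input"
    ds = _double_support(events_left, events_right)
    stats = block_stats(ds, block)
    if stats is not None:
        values[f"{src}_double_support_time_mean"] = stats[0]
    else:
        missing[f"{src}_double_support_time_mean"] = "insufficient_strides"
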