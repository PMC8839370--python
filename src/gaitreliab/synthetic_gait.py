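"""Synthetic three-sensor walking recordings with known ground truth.

The generator emulates the structure a foot-worn and a lumbar IMU see during
a two-minute walk: quasi-periodic impact transients at foot contact on the
vertical axis, swing-phase gyroscope bursts (foot pitch that integrates to
zero per stride), stance-phase quiescence, forward progression consistent
with a prescribed stride length, continuous medio-lateral sway at stride
frequency, lumbar step periodicity on AP/VT with an ML component whose sign
alternates with the stepping foot, additive white sensor noise, constant
gyroscope bias, and five-second stationary bookends.

Foot signals are produced by a consistent rigid-body model: world-frame
linear acceleration and a pitch trajectory are prescribed, and the sensor
stream is the specific force and angular rate expressed in the (optionally
yaw-mounted) sensor frame. Gravity removal and ZUPT therefore recover the
prescribed stride lengths rather than being fed them.

The generator also produces test-retest feature cohorts with a known
analytic ICC (between-subject variance over total variance) for validating
the reliability statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .config import GRAVITY
from .errors import ValidationError
from .io_preprocess import (PLACEMENTS, RawRecording, SensorStream, SubjectMeta,
                            write_recording)

Pair = Union[float, Tuple[float, float]]


def _pair(value: Pair) -> Tuple[float, float]:
    if isinstance(value, (tuple, list, np.ndarray)):
        left, right = float(value[0]), float(value[1])
    else:
        left = right = float(value)
    return left, right


@dataclass
class WalkSpec:
    """Parameters of one synthetic walking assessment.

    ``stride_time_mean_s``, ``stance_fraction`` and ``stride_length_m``
    accept either a scalar (symmetric gait) or a (left, right) pair.
    Temporal asymmetry within the gait cycle is controlled by
    ``step_time_ratio`` (left-step over right-step duration); per-foot
    stride times must still imply the same stride count +/-1 because the
    feet alternate.
    """

    duration_s: float = 120.0
    sample_rate_hz: float = 104.0
    stride_time_mean_s: Pair = 1.2
    stride_time_cv: float = 0.03
    step_time_ratio: float = 1.0
    stance_fraction: Pair = 0.6
    stride_length_m: Pair = 1.3
    impact_amplitude: float = 30.0         # m/s^2, vertical contact transient
    swing_gyro_amplitude: float = 200.0    # deg/s, foot pitch burst
    lateral_sway_amplitude: float = 1.0    # m/s^2, foot ML at stride frequency
    foot_lift_m: float = 0.04              # swing vertical excursion
    lumbar_ap_velocity_amp: float = 0.4    # m/s, AP velocity bump per step
    lumbar_vt_amplitude: float = 1.5       # m/s^2 at step frequency
    lumbar_ml_amplitude: float = 1.0       # m/s^2, alternates with stepping foot
    lumbar_gyro_amplitude: float = 10.0    # deg/s trunk yaw oscillation
    ml_positive_foot: str = "right"        # foot whose step has positive lumbar ML
    noise_sd_accel: float = 0.3            # m/s^2 white noise, all sensors
    noise_sd_gyro: float = 1.0             # deg/s white noise
    gyro_bias_dps: Optional[Dict[str, Sequence[float]]] = None
    standstill_bookend_s: float = 5.0
    mounting_yaw_deg: float = 0.0          # foot sensor yaw misalignment
    include_turns: bool = False            # 180-degree turn segments (off: the
    #                                        assessed protocol's turn handling is
    #                                        not modelled by default)
    subject_meta: SubjectMeta = field(default_factory=SubjectMeta)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        st_l, st_r = _pair(self.stride_time_mean_s)
        if st_l <= 0 or st_r <= 0:
            raise ValidationError("stride_time_mean_s", "must be positive")
        for name, lo, hi in (("stance_fraction", 0.0, 1.0),):
            for v in _pair(getattr(self, name)):
                if not lo < v < hi:
                    raise ValidationError(name, f"must be in ({lo}, {hi})")
        if self.duration_s <= 2 * self.standstill_bookend_s:
            raise ValidationError("duration_s",
                                  "must exceed twice the standstill bookend")
        if self.sample_rate_hz <= 0:
            raise ValidationError("sample_rate_hz", "must be positive")
        if self.stride_time_cv < 0:
            raise ValidationError("stride_time_cv", "must be non-negative")
        if self.step_time_ratio <= 0:
            raise ValidationError("step_time_ratio", "must be positive")
        if self.noise_sd_accel < 0 or self.noise_sd_gyro < 0:
            raise ValidationError("noise_sd_accel", "noise SDs must be non-negative")
        if self.ml_positive_foot not in ("left", "right"):
            raise ValidationError("ml_positive_foot", "must be 'left' or 'right'")
        walk = self.duration_s - 2 * self.standstill_bookend_s
        n_l, n_r = int(walk / st_l), int(walk / st_r)
        if abs(n_l - n_r) > 1:
            raise ValidationError(
                "stride_time_mean_s",
                f"per-foot stride times imply {n_l} vs {n_r} strides; the feet "
                "alternate, so counts may differ by at most 1")
        if self.include_turns:
            raise ValidationError("include_turns",
                                  "turn segments are not implemented")


@dataclass
class GroundTruth:
    """Simulated event times (seconds from recording start) per foot."""

    foot_contacts: Dict[str, np.ndarray]
    stance_intervals: Dict[str, np.ndarray]      # (n, 2) start/end seconds
    stride_lengths: Dict[str, np.ndarray]        # metres
    stationary_bounds: Tuple[float, float]       # (walk start, walk end)
    first_foot: str = "left"

    def __post_init__(self) -> None:
        for foot, c in self.foot_contacts.items():
            c = np.asarray(c, dtype=float)
            if np.any(np.diff(c) <= 0):
                raise ValidationError("foot_contacts",
                                      f"{foot}: events must strictly increase")
            self.foot_contacts[foot] = c
            iv = np.asarray(self.stance_intervals[foot], dtype=float)
            if iv.size and (np.any(iv[:, 1] <= iv[:, 0])
                            or np.any(iv[1:, 0] < iv[:-1, 1])):
                raise ValidationError("stance_intervals",
                                      f"{foot}: intervals must be ordered and disjoint")
            self.stance_intervals[foot] = iv
            if not iv.shape[0] in (c.size, c.size - 1):
                raise ValidationError(
                    "stance_intervals",
                    f"{foot}: {iv.shape[0]} stances for {c.size} contacts")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "foot_contacts": {k: v.tolist() for k, v in self.foot_contacts.items()},
            "stance_intervals": {k: v.tolist() for k, v in self.stance_intervals.items()},
            "stride_lengths": {k: v.tolist() for k, v in self.stride_lengths.items()},
            "stationary_bounds": list(self.stationary_bounds),
            "first_foot": self.first_foot,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            foot_contacts={k: np.array(v) for k, v in d["foot_contacts"].items()},
            stance_intervals={k: np.array(v).reshape(-1, 2)
                              for k, v in d["stance_intervals"].items()},
            stride_lengths={k: np.array(v) for k, v in d["stride_lengths"].items()},
            stationary_bounds=tuple(d["stationary_bounds"]),
            first_foot=d.get("first_foot", "left"),
        )


# ----------------------------------------------------------------------
# Event schedule
# ----------------------------------------------------------------------

def _schedule_events(spec: WalkSpec, rng: np.random.Generator
                     ) -> Tuple[Dict[str, np.ndarray], Dict[str, np.ndarray]]:
    """Contact times and stride durations per foot over the walking span."""
    st_l, st_r = _pair(spec.stride_time_mean_s)
    walk_start = spec.standstill_bookend_s
    walk_end = spec.duration_s - spec.standstill_bookend_s
    rho = spec.step_time_ratio
    swing_l = (1.0 - _pair(spec.stance_fraction)[0]) * st_l
    margin = 0.3

    def cumulate(start: float, mean: float) -> np.ndarray:
        times = [start]
        while True:
            jitter = np.clip(rng.standard_normal(), -2.5, 2.5)
            step = mean * max(0.2, 1.0 + spec.stride_time_cv * jitter)
            nxt = times[-1] + step
            if nxt > walk_end - margin:
                break
            times.append(nxt)
        return np.array(times)

    first_left = walk_start + swing_l
    left = cumulate(first_left, st_l)
    # the right contact is phase-locked within the left cycle: its offset
    # jitters around the step split but does not random-walk, as the feet
    # alternate within one shared cycle
    frac = rho / (1.0 + rho)
    drift = st_r - st_l  # honours a per-foot stride-time pair (bounded)
    rights = []
    for k, lc in enumerate(left):
        jitter = np.clip(rng.standard_normal(), -2.5, 2.5)
        offset = st_l * frac * (1.0 + spec.stride_time_cv * jitter) + k * drift
        offset = float(np.clip(offset, 0.2 * st_l, 0.8 * st_l))
        rc = lc + offset
        if rc > walk_end - margin:
            break
        rights.append(rc)
    right = np.array(rights)
    strides = {"left_foot": np.diff(left), "right_foot": np.diff(right)}
    return {"left_foot": left, "right_foot": right}, strides


# ----------------------------------------------------------------------
# Foot signal synthesis
# ----------------------------------------------------------------------

def _raised_cosine(tau: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * tau))


def _foot_world_motion(t: np.ndarray, contacts: np.ndarray,
                       stance_frac: float, stride_len: float,
                       spec: WalkSpec, stride_time_mean: float
                       ) -> Tuple[np.ndarray, np.ndarray]:
    """World-frame linear acceleration (AP, ML, VT) and pitch rate (deg/s)."""
    fs = spec.sample_rate_hz
    n = t.size
    accel = np.zeros((n, 3))          # columns AP, ML, VT
    pitch_rate = np.zeros(n)

    # swing preceding each contact, including the very first step-out
    strides = np.diff(contacts)
    for k, contact in enumerate(contacts):
        stride = strides[k - 1] if k > 0 else stride_time_mean
        t_sw = (1.0 - stance_frac) * stride
        s0 = contact - t_sw
        i0, i1 = int(np.ceil(s0 * fs)), int(np.floor(contact * fs))
        if i1 <= i0:
            continue
        seg = slice(i0, i1 + 1)
        tau = (t[seg] - s0) / t_sw
        # forward velocity bump integrating to one stride length
        v_peak = 2.0 * stride_len / t_sw
        accel[seg, 0] += v_peak * (np.pi / t_sw) * np.sin(2 * np.pi * tau)
        # vertical lift h = H sin^2(pi tau)
        h = spec.foot_lift_m
        accel[seg, 2] += h * 2.0 * (np.pi / t_sw) ** 2 * np.cos(2 * np.pi * tau)
        # pitch burst, zero net rotation over the swing
        pitch_rate[seg] += spec.swing_gyro_amplitude * np.sin(2 * np.pi * tau)

    # impact transient: one sine period, 50 ms, positive peak at contact
    dur = 0.05
    for contact in contacts:
        s0 = contact - dur / 4.0
        i0, i1 = int(np.ceil(s0 * fs)), int(np.floor((s0 + dur) * fs))
        seg = slice(max(i0, 0), min(i1 + 1, n))
        accel[seg, 2] += spec.impact_amplitude * np.sin(
            2 * np.pi * (t[seg] - s0) / dur)

    # continuous ML sway at stride frequency, tapered at the span edges
    if spec.lateral_sway_amplitude > 0 and contacts.size:
        f_stride = 1.0 / stride_time_mean
        span0 = contacts[0] - (1.0 - stance_frac) * stride_time_mean
        span1 = contacts[-1] + stance_frac * stride_time_mean
        win = np.clip((t - span0) / 0.5, 0, 1) * np.clip((span1 - t) / 0.5, 0, 1)
        accel[:, 1] += (spec.lateral_sway_amplitude * win
                        * np.sin(2 * np.pi * f_stride * (t - contacts[0])))
    return accel, pitch_rate


def _yaw_matrix(yaw_deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(yaw_deg)), np.sin(np.deg2rad(yaw_deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _foot_stream(t: np.ndarray, contacts: np.ndarray, stance_frac: float,
                 stride_len: float, stride_time_mean: float, spec: WalkSpec,
                 rng: np.random.Generator, bias: np.ndarray) -> SensorStream:
    accel_w, pitch_rate = _foot_world_motion(
        t, contacts, stance_frac, stride_len, spec, stride_time_mean)
    # integrate pitch (about the ML axis) to express gravity in the sensor frame
    theta = np.cumsum(np.deg2rad(pitch_rate)) / spec.sample_rate_hz
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    # specific force in world axes (x=AP, y=ML, z=VT): f = a - g, g=(0,0,-G)
    f_ap = accel_w[:, 0]
    f_ml = accel_w[:, 1]
    f_vt = accel_w[:, 2] + GRAVITY
    # body frame after pitch about ML: R_y(theta)^T f_world
    fb = np.column_stack([cos_t * f_ap - sin_t * f_vt,
                          f_ml,
                          sin_t * f_ap + cos_t * f_vt])
    gyro_b = np.column_stack([np.zeros_like(pitch_rate), pitch_rate,
                              np.zeros_like(pitch_rate)])
    r_m = _yaw_matrix(spec.mounting_yaw_deg)
    accel_s = fb @ r_m          # R_m^T applied row-wise
    gyro_s = gyro_b @ r_m
    accel_s = accel_s + rng.normal(0.0, spec.noise_sd_accel, accel_s.shape)
    gyro_s = gyro_s + bias + rng.normal(0.0, spec.noise_sd_gyro, gyro_s.shape)
    return SensorStream(accel=accel_s, gyro=gyro_s)


# ----------------------------------------------------------------------
# Lumbar signal synthesis
# ----------------------------------------------------------------------

def _lowback_stream(t: np.ndarray, contacts: Dict[str, np.ndarray],
                    spec: WalkSpec, rng: np.random.Generator,
                    bias: np.ndarray) -> SensorStream:
    fs = spec.sample_rate_hz
    n = t.size
    merged = sorted([(c, f) for f in ("left_foot", "right_foot")
                     for c in contacts[f]])
    times = np.array([c for c, _ in merged])
    feet = [f for _, f in merged]
    step_time = float(np.median(np.diff(times))) if times.size > 1 else 0.6

    accel = np.zeros((n, 3))  # AP, ML, VT
    # AP: derivative-of-Gaussian at each step so the integral peaks at contacts
    sigma = 0.05
    amp_v = spec.lumbar_ap_velocity_amp
    for c in times:
        seg = slice(max(0, int((c - 4 * sigma) * fs)),
                    min(n, int((c + 4 * sigma) * fs) + 1))
        dt_ = t[seg] - c
        accel[seg, 0] += amp_v * (-dt_ / sigma ** 2) * np.exp(-dt_ ** 2 / (2 * sigma ** 2))
    # VT: sinusoid at step frequency over the walking span
    span0, span1 = times[0] - step_time, times[-1] + step_time
    win = np.clip((t - span0) / 0.5, 0, 1) * np.clip((span1 - t) / 0.5, 0, 1)
    accel[:, 2] += (spec.lumbar_vt_amplitude * win
                    * np.sin(2 * np.pi * (t - times[0]) / step_time))
    # ML: sign alternates with the stepping foot (smoothed square wave)
    ml = np.zeros(n)
    for k, (c, foot) in enumerate(merged):
        end = merged[k + 1][0] if k + 1 < len(merged) else c + step_time
        sign = 1.0 if foot == f"{spec.ml_positive_foot}_foot" else -1.0
        i0, i1 = int(c * fs), min(int(end * fs), n)
        ml[i0:i1] = sign * spec.lumbar_ml_amplitude
    # soften edges with a short moving average
    k_smooth = max(1, int(0.05 * fs))
    kernel = np.ones(k_smooth) / k_smooth
    accel[:, 1] += np.convolve(ml, kernel, mode="same") * win

    accel[:, 2] += GRAVITY  # specific force; lumbar attitude stays level
    accel = accel + rng.normal(0.0, spec.noise_sd_accel, accel.shape)
    gyro = bias + rng.normal(0.0, spec.noise_sd_gyro, (n, 3))
    # small trunk yaw oscillation at step frequency: leaves gravity untouched
    # but gives the stationary-bound search real gyroscope contrast
    gyro[:, 2] += (spec.lumbar_gyro_amplitude * win
                   * np.sin(2 * np.pi * (t - times[0]) / step_time))
    return SensorStream(accel=accel, gyro=gyro)


# ----------------------------------------------------------------------
# Public API
# ----------------------------------------------------------------------

def generate_walk(spec: WalkSpec) -> Tuple[RawRecording, GroundTruth]:
    """Simulate one three-sensor walking assessment with ground truth."""
    rng = np.random.default_rng(spec.rng_seed)
    fs = spec.sample_rate_hz
    n = int(round(spec.duration_s * fs))
    t = np.arange(n) / fs

    contacts, strides = _schedule_events(spec, rng)
    st_l, st_r = _pair(spec.stride_time_mean_s)
    sf_l, sf_r = _pair(spec.stance_fraction)
    len_l, len_r = _pair(spec.stride_length_m)

    biases = {p: np.zeros(3) for p in PLACEMENTS}
    if spec.gyro_bias_dps:
        for p, b in spec.gyro_bias_dps.items():
            biases[p] = np.asarray(b, dtype=float)

    sensors = {
        "left_foot": _foot_stream(t, contacts["left_foot"], sf_l, len_l, st_l,
                                  spec, rng, biases["left_foot"]),
        "right_foot": _foot_stream(t, contacts["right_foot"], sf_r, len_r, st_r,
                                   spec, rng, biases["right_foot"]),
        "low_back": _lowback_stream(t, contacts, spec, rng, biases["low_back"]),
    }
    meta = SubjectMeta(
        subject_id=spec.subject_meta.subject_id,
        session_id=spec.subject_meta.session_id,
        height_m=spec.subject_meta.height_m,
        paretic_side=spec.subject_meta.paretic_side,
        expected_duration_s=spec.duration_s - 2 * spec.standstill_bookend_s,
    )
    recording = RawRecording(sensors=sensors, sample_rate_hz=fs, meta=meta)

    stances = {}
    lengths = {}
    for foot, sf, length, st_mean in (("left_foot", sf_l, len_l, st_l),
                                      ("right_foot", sf_r, len_r, st_r)):
        c = contacts[foot]
        durs = np.append(strides[foot], st_mean)
        stances[foot] = np.column_stack([c, c + sf * durs])
        lengths[foot] = np.full(max(c.size - 1, 0), length)
    first_contacts = {f: contacts[f][0] for f in ("left_foot", "right_foot")}
    first_foot = min(first_contacts, key=first_contacts.get).split("_")[0]
    walk_start = spec.standstill_bookend_s
    walk_end = max(contacts["left_foot"][-1], contacts["right_foot"][-1]) + 0.05
    truth = GroundTruth(foot_contacts=contacts, stance_intervals=stances,
                        stride_lengths=lengths,
                        stationary_bounds=(walk_start, walk_end),
                        first_foot=first_foot)
    return recording, truth


def write_walk(spec: WalkSpec, out_dir: str | Path,
               prefix: str = "walk") -> Tuple[Path, Path]:
    """Generate a walk and write recording CSVs + ground-truth JSON sidecar."""
    recording, truth = generate_walk(spec)
    manifest = write_recording(recording, out_dir, prefix=prefix)
    truth_path = Path(out_dir) / f"{prefix}_ground_truth.json"
    truth.to_json(truth_path)
    return manifest, truth_path


# ----------------------------------------------------------------------
# Test-retest cohorts
# ----------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Variance structure of a synthetic test-retest feature cohort."""

    n_subjects: int = 29
    sessions: int = 2
    between_subject_sd: float = 1.0
    within_subject_sd: float = 0.5
    feature_mean: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValidationError("n_subjects", "need at least 2 subjects")
        if self.sessions < 2:
            raise ValidationError("sessions", "need at least 2 sessions")
        if self.between_subject_sd < 0:
            raise ValidationError("between_subject_sd", "must be non-negative")
        if self.within_subject_sd < 0:
            raise ValidationError("within_subject_sd", "must be non-negative")
        if self.between_subject_sd == 0 and self.within_subject_sd == 0:
            raise ValidationError("between_subject_sd",
                                  "at least one variance component must be positive")

    @property
    def analytic_icc(self) -> float:
        b2 = self.between_subject_sd ** 2
        w2 = self.within_subject_sd ** 2
        return b2 / (b2 + w2)


def generate_cohort(cohort: CohortSpec) -> Tuple[np.ndarray, float]:
    """Subjects x sessions matrix drawn as subject effect + session noise.

    Returns the matrix together with its analytic ICC
    (between-variance / total variance).
    """
    rng = np.random.default_rng(cohort.rng_seed)
    subject = rng.normal(0.0, cohort.between_subject_sd, size=(cohort.n_subjects, 1))
    noise = rng.normal(0.0, cohort.within_subject_sd,
                       size=(cohort.n_subjects, cohort.sessions))
    return cohort.feature_mean + subject + noise, cohort.analytic_icc
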