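"""Raw-recording I/O, calibration, resampling, trimming and walk-bound search.

The preprocessing chain is fixed: (1) resample to 100 Hz, (2) subtract the
gyroscope bias estimated from a stationary calibration, (3) drop the first
and last two seconds (transitional movement), (4) locate the pre- and
post-walk stationary periods by thresholding the mean magnitudes of the
acceleration (minus gravity) and the gyroscope, (5) validate the residual
walking length against the expected duration with a strict ten-second bound.

Recordings travel as one CSV per sensor (``t,ax,ay,az,gx,gy,gz``; seconds,
m/s^2, deg/s) plus a JSON manifest mapping placements to files and carrying
subject metadata.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import resample_poly

from .config import GRAVITY, RunConfig
from .errors import CalibrationError, PreprocessError, ValidationError

log = logging.getLogger(__name__)

PLACEMENTS = ("left_foot", "right_foot", "low_back")
PARETIC_SIDES = ("left", "right", "both", "unknown")

CSV_COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz"]


@dataclass
class SubjectMeta:
    """Pass-through subject metadata used for normalisation."""

    subject_id: str = "anon"
    session_id: str = "1"
    height_m: float = 1.75
    paretic_side: str = "unknown"
    expected_duration_s: float = 120.0

    def __post_init__(self) -> None:
        if self.height_m <= 0:
            raise ValidationError("height_m", "must be positive")
        if self.paretic_side not in PARETIC_SIDES:
            raise ValidationError("paretic_side", f"must be one of {PARETIC_SIDES}")


@dataclass
class SensorStream:
    """One sensor's 6-channel stream: accel (N,3) m/s^2, gyro (N,3) deg/s."""

    accel: np.ndarray
    gyro: np.ndarray

    def __post_init__(self) -> None:
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.accel.ndim != 2 or self.accel.shape[1] != 3:
            raise ValidationError("accel", "must be an (N,3) array")
        if self.gyro.shape != self.accel.shape:
            raise ValidationError("gyro", "must match accel shape")

    @property
    def n_samples(self) -> int:
        return self.accel.shape[0]


@dataclass
class RawRecording:
    """One assessment: three time-synchronised 6-channel IMU streams."""

    sensors: Dict[str, SensorStream]
    sample_rate_hz: float
    meta: SubjectMeta = field(default_factory=SubjectMeta)

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValidationError("sample_rate_hz", "must be positive")
        missing = [p for p in PLACEMENTS if p not in self.sensors]
        if missing:
            raise ValidationError("sensors", f"missing sensor(s): {missing}")
        lengths = {p: s.n_samples for p, s in self.sensors.items()}
        if max(lengths.values()) - min(lengths.values()) > 1:
            raise ValidationError(
                "sensors", f"stream lengths differ by more than 1 sample: {lengths}")

    @property
    def duration_s(self) -> float:
        return self.sensors["left_foot"].n_samples / self.sample_rate_hz


@dataclass
class GyroBias:
    """Per-sensor gyroscope bias (deg/s 3-vectors)."""

    bias: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for placement, vec in self.bias.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (3,) or not np.all(np.isfinite(vec)):
                raise ValidationError("bias", f"{placement}: need a finite 3-vector")
            self.bias[placement] = vec

    @classmethod
    def zero(cls) -> "GyroBias":
        return cls({p: np.zeros(3) for p in PLACEMENTS})


@dataclass
class PreprocessedRecording:
    """Resampled, bias-corrected, trimmed recording with walking bounds."""

    sensors: Dict[str, SensorStream]
    sample_rate_hz: float
    meta: SubjectMeta
    walk_bounds: Tuple[int, int]                      # consensus, samples
    walk_bounds_per_sensor: Dict[str, Tuple[int, int]]

    @property
    def walk_duration_s(self) -> float:
        return (self.walk_bounds[1] - self.walk_bounds[0]) / self.sample_rate_hz


@dataclass
class LengthVerdict:
    """Outcome of the +/-10 s residual-length validation."""

    passed: bool
    deviations_s: Dict[str, float]
    combined_deviation_s: float
    expected_duration_s: float


# ----------------------------------------------------------------------
# CSV / manifest I/O
# ----------------------------------------------------------------------

def write_recording(rec: RawRecording, out_dir: str | Path,
                    prefix: str = "recording") -> Path:
    """Write one CSV per sensor plus a JSON manifest; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = {}
    n = min(s.n_samples for s in rec.sensors.values())
    t = np.arange(n) / rec.sample_rate_hz
    for placement, stream in rec.sensors.items():
        df = pd.DataFrame(
            np.column_stack([t, stream.accel[:n], stream.gyro[:n]]),
            columns=CSV_COLUMNS)
        fname = f"{prefix}_{placement}.csv"
        df.to_csv(out_dir / fname, index=False, float_format="%.6f")
        files[placement] = fname
    manifest = {
        "subject_id": rec.meta.subject_id,
        "session_id": rec.meta.session_id,
        "height_m": rec.meta.height_m,
        "paretic_side": rec.meta.paretic_side,
        "expected_duration_s": rec.meta.expected_duration_s,
        "sample_rate_hz": rec.sample_rate_hz,
        "sensors": files,
    }
    manifest_path = out_dir / f"{prefix}_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def read_recording(manifest_path: str | Path) -> RawRecording:
    """Load a recording from its JSON manifest."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    sensors = {}
    for placement in PLACEMENTS:
        if placement not in manifest.get("sensors", {}):
            raise ValidationError("sensors", f"manifest missing sensor {placement!r}")
        path = manifest_path.parent / manifest["sensors"][placement]
        if not path.exists():
            raise ValidationError("sensors", f"missing sensor file {path}")
        df = pd.read_csv(path)
        if list(df.columns) != CSV_COLUMNS:
            raise ValidationError("sensors", f"{path.name}: bad header {list(df.columns)}")
        sensors[placement] = SensorStream(
            accel=df[["ax", "ay", "az"]].to_numpy(),
            gyro=df[["gx", "gy", "gz"]].to_numpy())
    meta = SubjectMeta(
        subject_id=str(manifest.get("subject_id", "anon")),
        session_id=str(manifest.get("session_id", "1")),
        height_m=float(manifest.get("height_m", 1.75)),
        paretic_side=manifest.get("paretic_side", "unknown"),
        expected_duration_s=float(manifest.get("expected_duration_s", 120.0)),
    )
    return RawRecording(sensors=sensors,
                        sample_rate_hz=float(manifest["sample_rate_hz"]),
                        meta=meta)


# ----------------------------------------------------------------------
# Operations
# ----------------------------------------------------------------------

def estimate_gyro_bias(stationary: RawRecording,
                       motion_sd_threshold_dps: float = 2.0) -> GyroBias:
    """Per-axis mean gyroscope reading over a stationary calibration recording.

    Raises :class:`CalibrationError` if any axis of any sensor shows motion
    (standard deviation above ``motion_sd_threshold_dps``).
    """
    bias = {}
    for placement, stream in stationary.sensors.items():
        sd = stream.gyro.std(axis=0)
        if np.any(sd > motion_sd_threshold_dps):
            raise CalibrationError(
                f"{placement}: motion detected during calibration "
                f"(gyro SD {sd.round(2)} deg/s exceeds {motion_sd_threshold_dps})")
        bias[placement] = stream.gyro.mean(axis=0)
    return GyroBias(bias)


def _resample_stream(stream: SensorStream, fs_in: float, fs_out: float) -> SensorStream:
    if fs_in == fs_out:
        return SensorStream(stream.accel.copy(), stream.gyro.copy())
    frac = Fraction(fs_out / fs_in).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    return SensorStream(
        accel=resample_poly(stream.accel, up, down, axis=0),
        gyro=resample_poly(stream.gyro, up, down, axis=0))


def _stationary_mask(stream: SensorStream, fs: float, smooth_s: float) -> np.ndarray:
    """Boolean mask of samples below the mean-magnitude thresholds."""
    a_mag = np.abs(np.linalg.norm(stream.accel, axis=1) - GRAVITY)
    g_mag = np.linalg.norm(stream.gyro, axis=1)
    size = max(1, int(round(smooth_s * fs)))
    a_s = uniform_filter1d(a_mag, size=size, mode="nearest")
    g_s = uniform_filter1d(g_mag, size=size, mode="nearest")
    # absolute floors (well below any sensor noise) keep near-constant
    # signals stationary despite resampling ripple
    return (a_s < max(a_mag.mean(), 0.02)) & (g_s < max(g_mag.mean(), 0.02))


def _leading_run(mask: np.ndarray) -> int:
    idx = np.flatnonzero(~mask)
    return int(idx[0]) if idx.size else mask.size


def _walk_bounds(stream: SensorStream, fs: float, cfg: RunConfig,
                 placement: str) -> Tuple[int, int]:
    mask = _stationary_mask(stream, fs, cfg.stationary_smooth_s)
    n = mask.size
    lead = _leading_run(mask)
    trail = _leading_run(mask[::-1])
    if lead + trail >= n:
        raise PreprocessError(f"{placement}: no walking period found")
    min_run = int(round(cfg.stationary_min_s * fs))
    start = lead if lead >= min_run else 0
    end = n - trail if trail >= min_run else n
    if lead < min_run:
        log.warning("%s: no leading stationary period >= %.2f s found; "
                    "walk bound defaults to signal start", placement,
                    cfg.stationary_min_s)
    if trail < min_run:
        log.warning("%s: no trailing stationary period >= %.2f s found; "
                    "walk bound defaults to signal end", placement,
                    cfg.stationary_min_s)
    return start, end


def preprocess(raw: RawRecording, bias: Optional[GyroBias] = None,
               config: Optional[RunConfig] = None) -> PreprocessedRecording:
    """Resample to 100 Hz, subtract gyro bias, trim 2 s, find walk bounds."""
    cfg = config or RunConfig()
    bias = bias or GyroBias.zero()
    fs = cfg.target_rate_hz
    trim = int(round(cfg.trim_s * fs))
    min_len = 2 * (trim + int(round(cfg.stationary_min_s * fs)))
    sensors: Dict[str, SensorStream] = {}
    bounds: Dict[str, Tuple[int, int]] = {}
    for placement in PLACEMENTS:
        stream = _resample_stream(raw.sensors[placement], raw.sample_rate_hz, fs)
        stream = SensorStream(stream.accel, stream.gyro - bias.bias[placement])
        if stream.n_samples <= min_len:
            raise PreprocessError(
                f"{placement}: signal too short ({stream.n_samples} samples) for "
                f"2 x ({cfg.trim_s} s trim + {cfg.stationary_min_s} s bookend)")
        stream = SensorStream(stream.accel[trim:-trim], stream.gyro[trim:-trim])
        sensors[placement] = stream
        bounds[placement] = _walk_bounds(stream, fs, cfg, placement)
    # union of the walking spans: the assessment walks whenever any sensor does
    combined = (min(b[0] for b in bounds.values()),
                max(b[1] for b in bounds.values()))
    if combined[1] <= combined[0]:
        raise PreprocessError("no consensus walking period across sensors")
    return PreprocessedRecording(sensors=sensors, sample_rate_hz=fs, meta=raw.meta,
                                 walk_bounds=combined,
                                 walk_bounds_per_sensor=bounds)


def validate_length(pre: PreprocessedRecording,
                    expected_duration_s: Optional[float] = None,
                    tolerance_s: float = 10.0) -> LengthVerdict:
    """Strict >10 s residual-length exclusion rule, per sensor and combined.

    A measurement fails if ANY sensor's residual walking duration deviates
    from the expected duration by strictly more than the tolerance.
    """
    expected = (pre.meta.expected_duration_s if expected_duration_s is None
                else expected_duration_s)
    fs = pre.sample_rate_hz
    deviations = {
        p: (b[1] - b[0]) / fs - expected
        for p, b in pre.walk_bounds_per_sensor.items()
    }
    combined_dev = pre.walk_duration_s - expected
    passed = all(abs(d) <= tolerance_s for d in deviations.values()) \
        and abs(combined_dev) <= tolerance_s
    if not passed:
        log.info("length validation failed: deviations %s s (tolerance %s s)",
                 {k: round(v, 2) for k, v in deviations.items()}, tolerance_s)
    return LengthVerdict(passed=passed, deviations_s=deviations,
                         combined_deviation_s=combined_dev,
                         expected_duration_s=expected)
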