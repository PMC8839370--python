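"""Anatomical axis alignment, gravity removal, and ZUPT stride displacement.

Attitude is tracked with a gradient-descent (Madgwick-class) accelerometer/
gyroscope fusion filter. The quaternion is initialised from the quasi-static
lead-in (tilt from the mean gravity direction), acceleration is rotated to
the earth frame and the gravity vector subtracted, and the horizontal axes
are relabelled to anatomical AP/ML: the anterior-posterior direction is the
principal horizontal acceleration axis, signed by the direction of net
progression when one exists, otherwise by the initial mounting pose.
Conventions: VT upward positive, ML right positive, AP anterior positive.

Spatial stride features come from a zero-velocity update (ZUPT): gravity-free
acceleration is integrated between consecutive stance midpoints, the velocity
is linearly de-drifted so it is exactly zero at every stance anchor, and the
horizontal norm of the integrated displacement is the stride length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .config import GRAVITY, RunConfig
from .errors import OrientationError

DEG2RAD = np.pi / 180.0


@dataclass
class OrientedSignal:
    """Gravity-free acceleration and angular velocity in VT/ML/AP axes."""

    accel_vt: np.ndarray
    accel_ml: np.ndarray
    accel_ap: np.ndarray
    gyro_vt: np.ndarray
    gyro_ml: np.ndarray
    gyro_ap: np.ndarray
    sample_rate_hz: float
    source: str = "unknown"
    quaternions: Optional[np.ndarray] = None  # (N,4) w,x,y,z sensor->earth

    @property
    def n_samples(self) -> int:
        return self.accel_vt.size

    def accel_matrix(self) -> np.ndarray:
        """(N,3) array with columns (VT, ML, AP)."""
        return np.column_stack([self.accel_vt, self.accel_ml, self.accel_ap])

    def gyro_matrix(self) -> np.ndarray:
        return np.column_stack([self.gyro_vt, self.gyro_ml, self.gyro_ap])

    def accel_magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.accel_matrix(), axis=1)

    def gyro_magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.gyro_matrix(), axis=1)


# ----------------------------------------------------------------------
# Quaternion helpers (Hamilton convention, q = sensor -> earth)
# ----------------------------------------------------------------------

def _quat_from_two_vectors(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Shortest-arc quaternion rotating unit vector a onto unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    c = float(np.dot(a, b))
    if c < -1 + 1e-12:  # antiparallel: rotate 180 deg about any orthogonal axis
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-8:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return np.array([0.0, *axis])
    v = np.cross(a, b)
    q = np.array([1.0 + c, *v])
    return q / np.linalg.norm(q)


def _rotate_series(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate (N,3) sensor-frame vectors to earth frame by (N,4) quaternions."""
    w, x, y, z = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
    # rows of R(q) applied to v, vectorised
    vx, vy, vz = v[:, 0], v[:, 1], v[:, 2]
    rx = (1 - 2 * (y * y + z * z)) * vx + 2 * (x * y - w * z) * vy + 2 * (x * z + w * y) * vz
    ry = 2 * (x * y + w * z) * vx + (1 - 2 * (x * x + z * z)) * vy + 2 * (y * z - w * x) * vz
    rz = 2 * (x * z - w * y) * vx + 2 * (y * z + w * x) * vy + (1 - 2 * (x * x + y * y)) * vz
    return np.column_stack([rx, ry, rz])


def madgwick_filter(accel: np.ndarray, gyro_dps: np.ndarray, fs: float,
                    beta: float, q0: np.ndarray) -> np.ndarray:
    """Track sensor->earth attitude from accel (m/s^2) and gyro (deg/s).

    Returns the (N,4) quaternion trajectory (w,x,y,z). The accelerometer
    correction pulls the estimated gravity direction toward the measured
    specific force with gain ``beta``; the gyroscope drives the prediction.
    """
    n = accel.shape[0]
    dt = 1.0 / fs
    gyr = gyro_dps * DEG2RAD
    out = np.empty((n, 4))
    q1, q2, q3, q4 = (float(v) for v in q0)
    for i in range(n):
        gx, gy, gz = gyr[i, 0], gyr[i, 1], gyr[i, 2]
        ax, ay, az = accel[i, 0], accel[i, 1], accel[i, 2]
        # rate of change from gyroscope
        qd1 = 0.5 * (-q2 * gx - q3 * gy - q4 * gz)
        qd2 = 0.5 * (q1 * gx + q3 * gz - q4 * gy)
        qd3 = 0.5 * (q1 * gy - q2 * gz + q4 * gx)
        qd4 = 0.5 * (q1 * gz + q2 * gy - q3 * gx)
        norm = (ax * ax + ay * ay + az * az) ** 0.5
        if norm > 1e-9:
            ax, ay, az = ax / norm, ay / norm, az / norm
            # gradient of || R(q)^T e_z - a ||^2
            f1 = 2.0 * (q2 * q4 - q1 * q3) - ax
            f2 = 2.0 * (q1 * q2 + q3 * q4) - ay
            f3 = 2.0 * (0.5 - q2 * q2 - q3 * q3) - az
            s1 = -2.0 * q3 * f1 + 2.0 * q2 * f2
            s2 = 2.0 * q4 * f1 + 2.0 * q1 * f2 - 4.0 * q2 * f3
            s3 = -2.0 * q1 * f1 + 2.0 * q4 * f2 - 4.0 * q3 * f3
            s4 = 2.0 * q2 * f1 + 2.0 * q3 * f2
            snorm = (s1 * s1 + s2 * s2 + s3 * s3 + s4 * s4) ** 0.5
            if snorm > 1e-12:
                qd1 -= beta * s1 / snorm
                qd2 -= beta * s2 / snorm
                qd3 -= beta * s3 / snorm
                qd4 -= beta * s4 / snorm
        q1 += qd1 * dt
        q2 += qd2 * dt
        q3 += qd3 * dt
        q4 += qd4 * dt
        qn = (q1 * q1 + q2 * q2 + q3 * q3 + q4 * q4) ** 0.5
        q1, q2, q3, q4 = q1 / qn, q2 / qn, q3 / qn, q4 / qn
        out[i] = (q1, q2, q3, q4)
    return out


# ----------------------------------------------------------------------
# Axis resolution
# ----------------------------------------------------------------------

def _horizontal_axes(accel_earth: np.ndarray, q0: np.ndarray, fs: float,
                     span: Optional[Tuple[int, int]]) -> Tuple[np.ndarray, np.ndarray]:
    """Resolve AP and ML unit vectors in the earth horizontal plane.

    AP is the first principal axis of the horizontal gravity-free
    acceleration, signed so that the mean integrated velocity along it is
    positive (direction of progression). If there is no measurable
    progression, AP falls back to the initial mounting pose (sensor x-axis
    projected to horizontal).
    """
    s0, s1 = span if span is not None else (0, accel_earth.shape[0])
    h = accel_earth[s0:s1, :2]
    h = h - h.mean(axis=0)
    if h.shape[0] >= 2 and np.any(np.abs(h) > 1e-12):
        cov = h.T @ h
        evals, evecs = np.linalg.eigh(cov)
        u = evecs[:, np.argmax(evals)]
    else:
        u = np.array([1.0, 0.0])
    # sign: the initial mounting pose decides whenever it projects usably
    # onto the principal axis; otherwise the direction of net progression.
    # (Integrated accelerometer noise random-walks at ~0.2 m/s over two
    # minutes, so progression alone is unreliable for oscillatory signals.)
    x_earth = _rotate_series(q0[None, :], np.array([[1.0, 0.0, 0.0]]))[0]
    xh = x_earth[:2]
    pose_ok = np.linalg.norm(xh) > 0.5
    if pose_ok:
        xh = xh / np.linalg.norm(xh)
        pose_ok = abs(float(np.dot(u, xh))) > 0.3
    if pose_ok:
        if float(np.dot(u, xh)) < 0:
            u = -u
    else:
        v_along = cumulative_trapezoid(h @ u, dx=1.0 / fs, initial=0.0)
        if float(v_along.mean()) < 0:
            u = -u
    ap = np.array([u[0], u[1], 0.0])
    ml = np.cross([0.0, 0.0, 1.0], ap)  # ML = VT x AP (right positive)
    return ap, ml


def orient(accel: np.ndarray, gyro_dps: np.ndarray, sample_rate_hz: float,
           config: Optional[RunConfig] = None, source: str = "unknown",
           walk_span: Optional[Tuple[int, int]] = None) -> OrientedSignal:
    """Align a 6-channel stream with VT/ML/AP axes and remove gravity.

    Requires at least ``static_init_s`` seconds of quasi-static data at the
    start of the stream for the initial gravity estimate.
    """
    cfg = config or RunConfig()
    accel = np.asarray(accel, dtype=float)
    gyro_dps = np.asarray(gyro_dps, dtype=float)
    fs = sample_rate_hz
    n_init = int(round(cfg.static_init_s * fs))
    if accel.shape[0] < n_init:
        raise OrientationError("signal shorter than the static initialisation window")
    init_gyro = np.linalg.norm(gyro_dps[:n_init], axis=1)
    if init_gyro.mean() > cfg.static_gyro_max_dps:
        raise OrientationError(
            f"no quasi-static lead-in: mean gyro {init_gyro.mean():.1f} deg/s over "
            f"the first {cfg.static_init_s} s exceeds {cfg.static_gyro_max_dps}")
    g_sensor = accel[:n_init].mean(axis=0)
    if np.linalg.norm(g_sensor) < 0.5 * GRAVITY:
        raise OrientationError("initial accelerometer magnitude far from 1 g")
    q0 = _quat_from_two_vectors(g_sensor, np.array([0.0, 0.0, 1.0]))
    quats = madgwick_filter(accel, gyro_dps, fs, cfg.madgwick_beta, q0)
    accel_earth = _rotate_series(quats, accel)
    accel_earth[:, 2] -= GRAVITY
    gyro_earth = _rotate_series(quats, gyro_dps)
    ap, ml = _horizontal_axes(accel_earth, q0, fs, walk_span)
    return OrientedSignal(
        accel_vt=accel_earth[:, 2],
        accel_ml=accel_earth @ ml,
        accel_ap=accel_earth @ ap,
        gyro_vt=gyro_earth[:, 2],
        gyro_ml=gyro_earth @ ml,
        gyro_ap=gyro_earth @ ap,
        sample_rate_hz=fs,
        source=source,
        quaternions=quats,
    )


# ----------------------------------------------------------------------
# ZUPT
# ----------------------------------------------------------------------

@dataclass
class StrideDisplacement:
    """Per-stride ZUPT displacement (earth frame) and horizontal length."""

    displacements: np.ndarray   # (n_strides, 3): (VT, ML, AP) metres
    lengths: np.ndarray         # horizontal norm, metres
    anchors: np.ndarray         # stance-midpoint samples used


def zupt_stride_displacement(oriented: OrientedSignal,
                             stance_intervals: Sequence[Tuple[int, int]]
                             ) -> StrideDisplacement:
    """Integrate gravity-free acceleration between stance midpoints.

    Velocity is forced to zero at every stance midpoint by linear de-drift
    before the second integration; the stride length is the horizontal norm
    of the displacement between consecutive anchors.
    """
    fs = oriented.sample_rate_hz
    dt = 1.0 / fs
    acc = oriented.accel_matrix()  # columns VT, ML, AP
    anchors = np.array([(s + e) // 2 for s, e in stance_intervals], dtype=int)
    disp: List[np.ndarray] = []
    for k in range(len(anchors) - 1):
        s0, s1 = anchors[k], anchors[k + 1]
        if s1 <= s0 + 1:
            continue
        seg = acc[s0:s1 + 1]
        v = cumulative_trapezoid(seg, dx=dt, axis=0, initial=0.0)
        ramp = np.linspace(0.0, 1.0, v.shape[0])[:, None]
        v = v - ramp * v[-1]          # zero velocity at both stance anchors
        p = cumulative_trapezoid(v, dx=dt, axis=0, initial=0.0)
        disp.append(p[-1])
    if disp:
        d = np.vstack(disp)
        lengths = np.hypot(d[:, 1], d[:, 2])   # horizontal = (ML, AP)
    else:
        d = np.empty((0, 3))
        lengths = np.empty(0)
    return StrideDisplacement(displacements=d, lengths=lengths, anchors=anchors)
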