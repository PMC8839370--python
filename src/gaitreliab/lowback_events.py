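"""Gait events from the lumbar IMU via the foot-informed template procedure.

The anterior-posterior acceleration of the low back is integrated and
band-pass filtered (second-order Butterworth, 0.25-15 Hz, applied twice as a
zero-phase forward-backward pass), the first foot contact is found by peak
detection, the stepping foot is lateralised from the sign of the mean
medio-lateral acceleration over the first step, and the remaining contacts
are located by projecting the corresponding foot's inter-contact intervals
forward from the anchor and snapping to the nearest local AP maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.signal import argrelmax, butter, find_peaks, sosfiltfilt

from .config import RunConfig
from .errors import LowBackDetectionError, ValidationError
from .orientation import OrientedSignal
from .stride_detection import GaitEvents, RepairLog, StridePrior, height_threshold


@dataclass
class LowBackEvents:
    """Lumbar-derived contacts per foot with lateralisation provenance."""

    contact_samples: Dict[str, np.ndarray]
    first_foot: str
    sample_rate_hz: float
    template_source: str = "foot_events"
    missing_log: List[str] = field(default_factory=list)

    def merged_contacts(self) -> np.ndarray:
        return np.sort(np.concatenate(list(self.contact_samples.values())))

    def alternation_ok(self) -> bool:
        """True when merged left/right contacts strictly alternate."""
        tagged = sorted(
            [(s, f) for f, arr in self.contact_samples.items() for s in arr])
        feet = [f for _, f in tagged]
        return all(a != b for a, b in zip(feet[:-1], feet[1:]))

    def stride_times(self, foot: str) -> np.ndarray:
        return np.diff(self.contact_samples[foot]) / self.sample_rate_hz


# ----------------------------------------------------------------------
# Filtering
# ----------------------------------------------------------------------

def bandpass_filter(x: np.ndarray, sample_rate_hz: float,
                    band_hz: Tuple[float, float] = (0.25, 15.0),
                    order: int = 2) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth band-pass."""
    sos = butter(order, band_hz, btype="bandpass", fs=sample_rate_hz,
                 output="sos")
    return sosfiltfilt(sos, np.asarray(x, dtype=float))


def bandpass_ap(oriented_lowback: OrientedSignal,
                config: Optional[RunConfig] = None) -> np.ndarray:
    """Integrate the lumbar AP acceleration and band-pass it.

    ``lowback_ap_mode`` selects between the two readings of
    "integrated and filtered twice": the default integrates once and applies
    the filter as a single zero-phase (two-pass) operation; the alternate
    mode repeats integrate-then-filter twice.
    """
    cfg = config or RunConfig()
    fs = oriented_lowback.sample_rate_hz
    x = oriented_lowback.accel_ap
    y = cumulative_trapezoid(x, dx=1.0 / fs, initial=0.0)
    y = bandpass_filter(y, fs, cfg.lowback_band_hz, cfg.lowback_filter_order)
    if cfg.lowback_ap_mode == "integrate_twice":
        y = cumulative_trapezoid(y, dx=1.0 / fs, initial=0.0)
        y = bandpass_filter(y, fs, cfg.lowback_band_hz, cfg.lowback_filter_order)
    return y


# ----------------------------------------------------------------------
# Event detection
# ----------------------------------------------------------------------

def detect_first_contact(filtered_ap: np.ndarray, prior: StridePrior,
                         sample_rate_hz: float,
                         walk_bounds: Optional[Tuple[int, int]] = None,
                         config: Optional[RunConfig] = None) -> int:
    """First qualifying AP peak (distance 0.75 x stride time, height mean+SD)."""
    cfg = config or RunConfig()
    s0, s1 = (0, filtered_ap.size) if walk_bounds is None else walk_bounds
    distance = max(1, int(round(cfg.peak_distance_factor
                                * prior.average_stride_time_s * sample_rate_hz)))
    height = height_threshold(filtered_ap, walk_bounds)
    peaks, _ = find_peaks(filtered_ap[s0:s1], distance=distance, height=height)
    if peaks.size == 0:
        raise LowBackDetectionError("no qualifying AP peak found in the low back")
    return int(peaks[0] + s0)


def _other(foot: str) -> str:
    return "right_foot" if foot == "left_foot" else "left_foot"


def _snap_to_local_max(signal: np.ndarray, predicted: int, tol: int
                       ) -> Optional[int]:
    lo = max(predicted - tol, 1)
    hi = min(predicted + tol + 1, signal.size - 1)
    if hi <= lo:
        return None
    window = signal[lo - 1:hi + 1]
    local = argrelmax(window)[0]
    if local.size == 0:
        return None
    candidates = local + lo - 1
    return int(candidates[np.argmax(signal[candidates])])


def _match_template(filtered_ap: np.ndarray, anchor: int,
                    foot_contacts: np.ndarray, fs: float,
                    snap_frac: float, missing_log: List[str],
                    foot: str) -> np.ndarray:
    """Project the foot's inter-contact intervals forward from the anchor."""
    j0 = int(np.argmin(np.abs(foot_contacts - anchor)))
    intervals = np.diff(foot_contacts[j0:])
    contacts = [anchor]
    # predictions accumulate from the anchor, not from the previous snap:
    # a single snap onto a noise maximum must not re-centre the whole tail
    predicted = anchor
    for k, interval in enumerate(intervals):
        predicted += int(interval)
        if predicted >= filtered_ap.size:
            break
        tol = max(1, int(round(snap_frac * interval)))
        snapped = _snap_to_local_max(filtered_ap, predicted, tol)
        if snapped is None:
            missing_log.append(
                f"{foot}: no local AP maximum within +/-{tol} samples of "
                f"predicted contact {predicted} (template step {k})")
            continue
        contacts.append(snapped)
    return np.asarray(contacts, dtype=int)


def lateralize_and_match(filtered_ap: np.ndarray, ml_accel: np.ndarray,
                         foot_events_left: Optional[GaitEvents],
                         foot_events_right: Optional[GaitEvents],
                         first_contact: int, prior: StridePrior,
                         sample_rate_hz: float,
                         config: Optional[RunConfig] = None) -> LowBackEvents:
    """Assign the first foot from the ML sign, then template-match both feet."""
    cfg = config or RunConfig()
    if foot_events_left is None or foot_events_right is None:
        raise ValidationError("foot_events", "template unavailable: stride "
                              "detection of both feet is required")
    fs = sample_rate_hz
    step = max(1, int(round(0.5 * prior.average_stride_time_s * fs)))
    window = ml_accel[first_contact:first_contact + step]
    if window.size == 0:
        raise LowBackDetectionError("first contact too close to the signal end")
    positive = float(window.mean()) > 0
    first_foot = (cfg.ml_positive_foot if positive
                  else _other(cfg.ml_positive_foot + "_foot").split("_")[0])
    events = {"left": foot_events_left, "right": foot_events_right}
    missing: List[str] = []

    contacts: Dict[str, np.ndarray] = {}
    contacts[first_foot] = _match_template(
        filtered_ap, first_contact, events[first_foot].contact_samples, fs,
        cfg.snap_tolerance_frac, missing, first_foot)

    # anchor the other foot between the first and second contact of the first
    second_foot = _other(first_foot + "_foot").split("_")[0]
    if contacts[first_foot].size >= 2:
        lo, hi = int(contacts[first_foot][0]), int(contacts[first_foot][1])
    else:
        lo, hi = first_contact, min(first_contact + 2 * step, filtered_ap.size)
    inner = filtered_ap[lo + 1:hi]
    local = argrelmax(inner)[0]
    if local.size == 0:
        raise LowBackDetectionError(
            f"no {second_foot}-foot anchor peak between the first two "
            f"{first_foot}-foot contacts")
    anchor2 = int(local[np.argmax(inner[local])] + lo + 1)
    contacts[second_foot] = _match_template(
        filtered_ap, anchor2, events[second_foot].contact_samples, fs,
        cfg.snap_tolerance_frac, missing, second_foot)

    out = LowBackEvents(
        contact_samples={f"{k}_foot": v for k, v in contacts.items()},
        first_foot=first_foot, sample_rate_hz=fs, missing_log=missing)
    if not out.alternation_ok():
        missing.append("merged low-back contacts do not strictly alternate")
    return out


def detect_lowback_events(oriented_lowback: OrientedSignal,
                          foot_events_left: GaitEvents,
                          foot_events_right: GaitEvents,
                          prior: StridePrior,
                          walk_bounds: Optional[Tuple[int, int]] = None,
                          config: Optional[RunConfig] = None) -> LowBackEvents:
    """Full lumbar event detection chain."""
    cfg = config or RunConfig()
    fs = oriented_lowback.sample_rate_hz
    filtered = bandpass_ap(oriented_lowback, cfg)
    first = detect_first_contact(filtered, prior, fs, walk_bounds, cfg)
    return lateralize_and_match(filtered, oriented_lowback.accel_ml,
                                foot_events_left, foot_events_right,
                                first, prior, fs, cfg)
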