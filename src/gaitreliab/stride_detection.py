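"""Foot stride, stance and swing detection robust to slow and asymmetric gait.

Pipeline per foot:

1. a stride-time prior from the dominant frequency of the medio-lateral
   acceleration (FFT, searched in a configurable band);
2. foot-contact candidates from peak detection in the vertical acceleration
   with minimum distance 0.75 x the average stride time and minimum height
   mean + SD of the vertical acceleration;
3. a false-negative pass: every inter-peak gap exceeding 1.5 x the expected
   stride time is re-searched with the height threshold scaled by 0.75;
4. stance phases as the longest quiescent span (>= 0.2 s below the
   acceleration mean + SD and the gyroscope mean magnitude thresholds)
   between consecutive contacts, with a false-positive pass that removes the
   lowest of the two bounding peaks whenever no quiescent span exists;
5. swing phases as the complement between stances.

Thresholds are computed over the walking span only, so the stationary
bookends do not depress them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, welch

from .config import RunConfig
from .errors import DetectionError, PriorEstimationError
from .orientation import OrientedSignal


@dataclass
class StridePrior:
    """Average stride time from the dominant ML-acceleration frequency."""

    average_stride_time_s: float
    dominant_frequency_hz: float

    def __post_init__(self) -> None:
        if not np.isclose(self.average_stride_time_s * self.dominant_frequency_hz,
                          1.0, rtol=1e-6):
            raise ValueError("stride time must be the reciprocal of the "
                             "dominant frequency")


@dataclass
class RepairLog:
    false_negative_insertions: int = 0
    false_positive_removals: int = 0
    spacing_violations: int = 0


@dataclass
class GaitEvents:
    """Per-foot contacts plus stance/swing segmentation (sample indices)."""

    foot: str
    contact_samples: np.ndarray
    stance_intervals: List[Tuple[int, int]]
    swing_intervals: List[Tuple[int, int]]
    sample_rate_hz: float
    repair_log: RepairLog = field(default_factory=RepairLog)
    source: str = "foot"

    @property
    def n_strides(self) -> int:
        return max(self.contact_samples.size - 1, 0)

    def contact_times(self) -> np.ndarray:
        return self.contact_samples / self.sample_rate_hz

    def stride_times(self) -> np.ndarray:
        return np.diff(self.contact_samples) / self.sample_rate_hz

    def stance_durations(self) -> np.ndarray:
        return np.array([(e - s) / self.sample_rate_hz
                         for s, e in self.stance_intervals])

    def swing_durations(self) -> np.ndarray:
        return np.array([(e - s) / self.sample_rate_hz
                         for s, e in self.swing_intervals])

    def to_dataframe(self) -> pd.DataFrame:
        rows = [(self.foot, "contact", int(s), s / self.sample_rate_hz, self.source)
                for s in self.contact_samples]
        for label, ivs in (("stance_start", [s for s, _ in self.stance_intervals]),
                           ("stance_end", [e for _, e in self.stance_intervals]),
                           ("swing_start", [s for s, _ in self.swing_intervals]),
                           ("swing_end", [e for _, e in self.swing_intervals])):
            rows += [(self.foot, label, int(s), s / self.sample_rate_hz, self.source)
                     for s in ivs]
        df = pd.DataFrame(rows, columns=["foot", "event", "sample", "time_s", "source"])
        return df.sort_values(["sample", "event"]).reset_index(drop=True)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


# ----------------------------------------------------------------------
# Stride-time prior
# ----------------------------------------------------------------------

def estimate_stride_prior(ml_accel: np.ndarray, sample_rate_hz: float,
                          config: Optional[RunConfig] = None) -> StridePrior:
    """Dominant ML-acceleration frequency -> average stride time.

    A Welch-averaged periodogram provides a flatness check (the dominant peak
    must exceed ``prior_peak_min_ratio`` x the in-band median); the peak
    location is then refined on a fine zero-padded FFT so short stride-time
    differences remain resolvable.
    """
    cfg = config or RunConfig()
    x = np.asarray(ml_accel, dtype=float)
    fs = sample_rate_hz
    if x.size < 10 * fs:
        raise PriorEstimationError("need at least 10 s of walking signal")
    x = x - x.mean()
    lo, hi = cfg.prior_band_hz

    nperseg = min(x.size, int(round(cfg.welch_segment_s * fs)))
    freqs_w, psd = welch(x, fs=fs, nperseg=nperseg)
    band_w = (freqs_w >= lo) & (freqs_w <= hi)
    if not np.any(band_w):
        raise PriorEstimationError("frequency band empty at this sample rate")
    peak_w = float(np.max(psd[band_w]))
    median_w = float(np.median(psd[band_w]))
    if median_w <= 0 or peak_w < cfg.prior_peak_min_ratio * median_w:
        raise PriorEstimationError(
            "spectrum flat: no dominant peak exceeding "
            f"{cfg.prior_peak_min_ratio} x the median magnitude")
    f_coarse = float(freqs_w[band_w][np.argmax(psd[band_w])])
    df_w = freqs_w[1] - freqs_w[0]

    n_fft = int(2 ** np.ceil(np.log2(x.size * 4)))
    mag = np.abs(np.fft.rfft(x, n=n_fft))
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / fs)
    fine = (freqs >= max(lo, f_coarse - df_w)) & (freqs <= min(hi, f_coarse + df_w))
    f_dom = float(freqs[fine][np.argmax(mag[fine])])

    stride = float(np.clip(1.0 / f_dom, *cfg.prior_bounds_s))
    return StridePrior(average_stride_time_s=stride,
                       dominant_frequency_hz=1.0 / stride)


# ----------------------------------------------------------------------
# Peak detection and repairs
# ----------------------------------------------------------------------

def _span(n: int, walk_bounds: Optional[Tuple[int, int]]) -> Tuple[int, int]:
    return (0, n) if walk_bounds is None else walk_bounds


def height_threshold(vt_accel: np.ndarray,
                     walk_bounds: Optional[Tuple[int, int]] = None) -> float:
    """Minimum peak height: mean + SD of the vertical acceleration."""
    s0, s1 = _span(vt_accel.size, walk_bounds)
    seg = vt_accel[s0:s1]
    return float(seg.mean() + seg.std())


def detect_foot_contacts(vt_accel: np.ndarray, prior: StridePrior,
                         sample_rate_hz: float,
                         walk_bounds: Optional[Tuple[int, int]] = None,
                         config: Optional[RunConfig] = None) -> np.ndarray:
    """Peak detection with distance 0.75 x stride time and height mean + SD."""
    cfg = config or RunConfig()
    s0, s1 = _span(vt_accel.size, walk_bounds)
    distance = max(1, int(round(cfg.peak_distance_factor
                                * prior.average_stride_time_s * sample_rate_hz)))
    height = height_threshold(vt_accel, walk_bounds)
    peaks, _ = find_peaks(vt_accel[s0:s1], distance=distance, height=height)
    return peaks + s0


def repair_false_negatives(candidates: np.ndarray, vt_accel: np.ndarray,
                           prior: StridePrior, sample_rate_hz: float,
                           walk_bounds: Optional[Tuple[int, int]] = None,
                           config: Optional[RunConfig] = None,
                           repair_log: Optional[RepairLog] = None) -> np.ndarray:
    """Re-search gaps > 1.5 x stride time with 0.75 x the height threshold."""
    cfg = config or RunConfig()
    candidates = np.asarray(candidates, dtype=int)
    if candidates.size < 2:
        return candidates
    fs = sample_rate_hz
    gap_limit = cfg.gap_factor * prior.average_stride_time_s * fs
    distance = max(1, int(round(cfg.peak_distance_factor
                                * prior.average_stride_time_s * fs)))
    height = cfg.fn_height_factor * height_threshold(vt_accel, walk_bounds)
    inserted: List[int] = []
    for left, right in zip(candidates[:-1], candidates[1:]):
        if right - left <= gap_limit:
            continue
        # search only where an inserted peak can satisfy the minimum
        # distance to both bounding contacts; peaks outside that region
        # could never be kept and must not shadow valid ones
        lo, hi = left + distance, right - distance + 1
        if hi <= lo:
            continue
        seg = vt_accel[max(lo - 1, 0):hi + 1]   # one-sample context for edges
        peaks, _ = find_peaks(seg, distance=distance, height=height)
        peaks = peaks + max(lo - 1, 0)
        inserted.extend(int(p) for p in peaks if lo <= p < hi)
    if repair_log is not None:
        repair_log.false_negative_insertions += len(inserted)
    return np.unique(np.concatenate([candidates, np.array(inserted, dtype=int)]))


# ----------------------------------------------------------------------
# Stance / swing segmentation
# ----------------------------------------------------------------------

def _quiescent_mask(accel_mag: np.ndarray, gyro_mag: np.ndarray,
                    walk_bounds: Optional[Tuple[int, int]]) -> np.ndarray:
    s0, s1 = _span(accel_mag.size, walk_bounds)
    thr_a = accel_mag[s0:s1].mean() + accel_mag[s0:s1].std()
    thr_g = gyro_mag[s0:s1].mean()
    return (accel_mag < thr_a) & (gyro_mag < thr_g)


def _longest_run(mask: np.ndarray, min_len: int) -> Optional[Tuple[int, int]]:
    """Longest True run of at least ``min_len`` samples; local indices."""
    if not mask.any():
        return None
    padded = np.concatenate([[0], mask.astype(int), [0]])
    edges = np.flatnonzero(np.diff(padded))
    starts, ends = edges[::2], edges[1::2]
    lengths = ends - starts
    best = int(np.argmax(lengths))
    if lengths[best] < min_len:
        return None
    return int(starts[best]), int(ends[best])


def segment_stance_swing(contacts: np.ndarray, accel_mag: np.ndarray,
                         gyro_mag: np.ndarray, sample_rate_hz: float,
                         foot: str = "unknown",
                         walk_bounds: Optional[Tuple[int, int]] = None,
                         config: Optional[RunConfig] = None,
                         repair_log: Optional[RepairLog] = None) -> GaitEvents:
    """Quiescence-based stance segmentation with false-positive peak removal.

    Between consecutive contacts the longest span of at least 0.2 s below
    both magnitude thresholds becomes the stance (its start is anchored to
    the leading contact, so stance and swing tile the detected span). When a
    gap has no qualifying span, the lower of its two bounding peaks is
    removed and segmentation restarts.
    """
    cfg = config or RunConfig()
    fs = sample_rate_hz
    log = repair_log if repair_log is not None else RepairLog()
    contacts = np.asarray(sorted(set(int(c) for c in contacts)), dtype=int)
    if contacts.size < 2:
        raise DetectionError(f"{foot}: need at least two contacts")
    quiescent = _quiescent_mask(accel_mag, gyro_mag, walk_bounds)
    min_len = max(1, int(round(cfg.stance_min_s * fs)))

    while True:
        if contacts.size < 2:
            raise DetectionError(
                f"{foot}: no stance phase anywhere (continuous motion?)")
        stance_ends: List[Optional[int]] = []
        bad_gap = None
        for i, (left, right) in enumerate(zip(contacts[:-1], contacts[1:])):
            run = _longest_run(quiescent[left:right], min_len)
            if run is None:
                bad_gap = i
                break
            stance_ends.append(left + run[1])
        if bad_gap is None:
            break
        left, right = contacts[bad_gap], contacts[bad_gap + 1]
        drop = bad_gap if accel_mag[left] <= accel_mag[right] else bad_gap + 1
        contacts = np.delete(contacts, drop)
        log.false_positive_removals += 1

    stances = [(int(c), int(e)) for c, e in zip(contacts[:-1], stance_ends)]
    swings = [(e, int(nxt)) for (_, e), nxt in zip(stances, contacts[1:])]
    swings = [(s, e) for s, e in swings if e > s]

    min_spacing = cfg.peak_distance_factor * _prior_from_contacts(contacts, fs)
    violations = int(np.sum(np.diff(contacts) / fs < min_spacing))
    log.spacing_violations += violations

    return GaitEvents(foot=foot, contact_samples=contacts,
                      stance_intervals=stances, swing_intervals=swings,
                      sample_rate_hz=fs, repair_log=log)


def _prior_from_contacts(contacts: np.ndarray, fs: float) -> float:
    d = np.diff(contacts)
    return float(np.median(d) / fs) if d.size else 0.0


# ----------------------------------------------------------------------
# End-to-end per foot
# ----------------------------------------------------------------------

def detect_gait_events(oriented: OrientedSignal, sample_rate_hz: float,
                       foot: str = "unknown",
                       walk_bounds: Optional[Tuple[int, int]] = None,
                       config: Optional[RunConfig] = None,
                       prior: Optional[StridePrior] = None) -> GaitEvents:
    """Full stride detection for one foot from its oriented signal."""
    cfg = config or RunConfig()
    s0, s1 = _span(oriented.n_samples, walk_bounds)
    if prior is None:
        prior = estimate_stride_prior(oriented.accel_ml[s0:s1], sample_rate_hz, cfg)
    log = RepairLog()
    contacts = detect_foot_contacts(oriented.accel_vt, prior, sample_rate_hz,
                                    walk_bounds, cfg)
    contacts = repair_false_negatives(contacts, oriented.accel_vt, prior,
                                      sample_rate_hz, walk_bounds, cfg, log)
    if contacts.size < 2:
        raise DetectionError(f"{foot}: fewer than two foot contacts detected")
    events = segment_stance_swing(contacts, oriented.accel_magnitude(),
                                  oriented.gyro_magnitude(), sample_rate_hz,
                                  foot=foot, walk_bounds=walk_bounds,
                                  config=cfg, repair_log=log)
    return events


def export_events_csv(events: Sequence[GaitEvents], path: str | Path) -> None:
    """Write several feet's events into one inspection CSV."""
    pd.concat([e.to_dataframe() for e in events]).to_csv(path, index=False)
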