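"""Spectral gait features from Welch-averaged periodograms.

Per catalogue axis: dominant frequency (parabolically interpolated),
dominant-peak amplitude, width (the frequency span around the dominant peak
holding a configured fraction of the in-band power) and density (dominant
peak power over total in-band power). The low back additionally carries an
index of harmonicity (power at the dominant frequency over the first six
harmonics) and a harmonic ratio (even over odd harmonics of the stride
frequency, the classic trunk-accelerometry smoothness measure; odd over even
on the medio-lateral axis), plus the signal-magnitude features (RMS and
range per axis).
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np
from scipy.signal import welch

from ..config import RunConfig
from ..orientation import OrientedSignal

Values = Dict[str, float]
Missing = Dict[str, str]

FOOT_MEASURES = ("dominant_frequency", "dominant_amplitude",
                 "dominant_width", "dominant_density")
LOWBACK_MEASURES = FOOT_MEASURES + ("harmonicity_index", "harmonic_ratio")


def _parabolic(freqs: np.ndarray, psd: np.ndarray, i: int) -> float:
    if i <= 0 or i >= psd.size - 1:
        return float(freqs[i])
    y0, y1, y2 = psd[i - 1], psd[i], psd[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(freqs[i])
    delta = 0.5 * (y0 - y2) / denom
    return float(freqs[i] + delta * (freqs[1] - freqs[0]))


def _peak_region(psd: np.ndarray, i: int) -> Tuple[int, int]:
    """Contiguous bins around i while the spectrum keeps descending."""
    lo = i
    while lo > 0 and psd[lo - 1] < psd[lo]:
        lo -= 1
    hi = i
    while hi < psd.size - 1 and psd[hi + 1] < psd[hi]:
        hi += 1
    return lo, hi


def _width(psd: np.ndarray, i: int, fraction: float, df: float) -> float:
    """Greedy span around the peak holding ``fraction`` of the band power."""
    total = psd.sum()
    lo = hi = i
    acc = psd[i]
    while acc < fraction * total and (lo > 0 or hi < psd.size - 1):
        left = psd[lo - 1] if lo > 0 else -np.inf
        right = psd[hi + 1] if hi < psd.size - 1 else -np.inf
        if left >= right:
            lo -= 1
            acc += psd[lo]
        else:
            hi += 1
            acc += psd[hi]
    return (hi - lo + 1) * df


def _harmonic_power(freqs: np.ndarray, psd: np.ndarray, f: float) -> float:
    """Power in the +/- one-bin neighbourhood of frequency f."""
    if f <= 0 or f > freqs[-1]:
        return 0.0
    i = int(np.argmin(np.abs(freqs - f)))
    lo, hi = max(i - 1, 0), min(i + 2, psd.size)
    return float(psd[lo:hi].sum())


def _axis_features(x: np.ndarray, fs: float, cfg: RunConfig,
                   stride_freq_hz: Optional[float], with_harmonics: bool
                   ) -> Optional[Values]:
    """None signals a flat spectrum (features missing)."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    nperseg = min(x.size, int(round(cfg.welch_segment_s * fs)))
    freqs, psd = welch(x, fs=fs, nperseg=nperseg)
    df = freqs[1] - freqs[0]
    lo_f, hi_f = cfg.freq_band_hz
    band = (freqs >= lo_f) & (freqs <= hi_f)
    fb, pb = freqs[band], psd[band]
    if pb.size < 3:
        return None
    i = int(np.argmax(pb))
    if np.median(pb) <= 0 or pb[i] < cfg.prior_peak_min_ratio * np.median(pb):
        return None
    out: Values = {}
    out["dominant_frequency"] = _parabolic(fb, pb, i)
    r0, r1 = _peak_region(pb, i)
    peak_power = pb[r0:r1 + 1].sum() * df
    out["dominant_amplitude"] = float(np.sqrt(2.0 * peak_power))
    out["dominant_width"] = float(_width(pb, i, cfg.freq_power_fraction, df))
    out["dominant_density"] = float(pb[r0:r1 + 1].sum() / pb.sum())
    if with_harmonics:
        f0 = out["dominant_frequency"]
        fundamental = _harmonic_power(freqs, psd, f0)
        harmonics = sum(_harmonic_power(freqs, psd, k * f0)
                        for k in range(1, 7))
        out["harmonicity_index"] = (fundamental / harmonics
                                    if harmonics > 0 else np.nan)
        if stride_freq_hz and stride_freq_hz > 0:
            even = sum(np.sqrt(_harmonic_power(freqs, psd, k * stride_freq_hz))
                       for k in range(2, 21, 2))
            odd = sum(np.sqrt(_harmonic_power(freqs, psd, k * stride_freq_hz))
                      for k in range(1, 21, 2))
            out["harmonic_ratio"] = even / odd if odd > 0 else np.nan
        else:
            out["harmonic_ratio"] = np.nan
    return out


def frequency_features(oriented: Dict[str, OrientedSignal],
                       walk_bounds: Optional[Tuple[int, int]] = None,
                       config: Optional[RunConfig] = None,
                       stride_freq_hz: Optional[float] = None
                       ) -> Tuple[Values, Missing]:
    """All 26 frequency features plus the 7 low-back magnitude features."""
    cfg = config or RunConfig()
    values: Values = {}
    missing: Missing = {}

    def emit(source: str, axis: str, measures, x, fs) -> None:
        feats = _axis_features(x, fs, cfg, stride_freq_hz,
                               with_harmonics="harmonicity_index" in measures)
        for m in measures:
            name = f"{source}_{axis}_{m}"
            if feats is None:
                missing[name] = "flat_spectrum"
            elif np.isnan(feats.get(m, np.nan)):
                missing[name] = "undefined_harmonics"
            else:
                values[name] = feats[m]

    for source, sig in oriented.items():
        fs = sig.sample_rate_hz
        s0, s1 = (0, sig.n_samples) if walk_bounds is None else walk_bounds
        span_s = (s1 - s0) / fs
        axes = {"vt": sig.accel_vt[s0:s1], "ml": sig.accel_ml[s0:s1],
                "ap": sig.accel_ap[s0:s1]}
        if source in ("left_foot", "right_foot"):
            targets = {"vt": FOOT_MEASURES}
        else:
            targets = {a: LOWBACK_MEASURES for a in ("vt", "ml", "ap")}
        if span_s < cfg.min_frequency_span_s:
            for axis, measures in targets.items():
                for m in measures:
                    missing[f"{source}_{axis}_{m}"] = "insufficient_span"
        else:
            for axis, measures in targets.items():
                emit(source, axis, measures, axes[axis], fs)
        if source == "low_back":
            for axis, x in axes.items():
                values[f"{source}_{axis}_rms"] = float(np.sqrt(np.mean(
                    (x - x.mean()) ** 2)))
                values[f"{source}_{axis}_range"] = float(np.ptp(x))
            centred = np.column_stack([v - v.mean() for v in axes.values()])
            values[f"{source}_rms_total"] = float(
                np.sqrt(np.mean(np.sum(centred ** 2, axis=1))))
    return values, missing
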