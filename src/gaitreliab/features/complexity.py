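"""Nonlinear / regularity features over a fixed 25-stride window.

Each axis is time-normalised to a fixed number of samples per stride (the
first 25 strides only, regardless of how much more data exists), then:

- sample entropy and approximate entropy (m = 2, r = 0.2 x SD, Chebyshev
  distance);
- unbiased autocorrelation and autocovariance at one-stride and one-step
  lags;
- the largest Lyapunov exponent by the divergence-curve method (delay
  embedding, nearest neighbours outside a one-stride Theiler window, least-
  squares slope of the mean log divergence over the first half stride),
  reported per stride.

Fewer than 25 strides yields missing features with a reason code, never an
exception.
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np
from scipy.spatial.distance import cdist

from ..config import RunConfig
from ..orientation import OrientedSignal
from ..stride_detection import GaitEvents

Values = Dict[str, float]
Missing = Dict[str, str]

_CHUNK = 512


def _count_matches(templates: np.ndarray, r: float, include_self: bool
                   ) -> np.ndarray:
    """Per-template count of Chebyshev matches within r (chunked O(N^2))."""
    n = templates.shape[0]
    counts = np.zeros(n, dtype=np.int64)
    for start in range(0, n, _CHUNK):
        chunk = templates[start:start + _CHUNK]
        d = np.abs(chunk[:, None, :] - templates[None, :, :]).max(axis=2)
        counts[start:start + _CHUNK] = (d <= r).sum(axis=1)
    if not include_self:
        counts -= 1
    return counts


def _embed(x: np.ndarray, m: int, tau: int = 1) -> np.ndarray:
    n = x.size - (m - 1) * tau
    return np.column_stack([x[i * tau:i * tau + n] for i in range(m)])


def sample_entropy(x: np.ndarray, m: int = 2, r: Optional[float] = None) -> float:
    """SampEn(m, r): -ln(A/B) over self-match-excluded template pairs."""
    x = np.asarray(x, dtype=float)
    if r is None:
        r = 0.2 * x.std()
    # truncate to equal template counts so A and B pair up
    b = _count_matches(_embed(x, m)[:-1], r, include_self=False).sum()
    a = _count_matches(_embed(x, m + 1), r, include_self=False).sum()
    if b == 0 or a == 0:
        return np.inf
    return float(-np.log(a / b))


def approximate_entropy(x: np.ndarray, m: int = 2,
                        r: Optional[float] = None) -> float:
    """ApEn(m, r) = phi(m) - phi(m+1) with self-matches included."""
    x = np.asarray(x, dtype=float)
    if r is None:
        r = 0.2 * x.std()

    def phi(mm: int) -> float:
        templates = _embed(x, mm)
        counts = _count_matches(templates, r, include_self=True)
        return float(np.mean(np.log(counts / templates.shape[0])))

    return phi(m) - phi(m + 1)


def lagged_autocovariance(x: np.ndarray, lag: int) -> float:
    """Unbiased autocovariance at the given lag."""
    x = np.asarray(x, dtype=float)
    mu = x.mean()
    d = x - mu
    return float(np.dot(d[:-lag], d[lag:]) / (x.size - lag))


def lagged_autocorrelation(x: np.ndarray, lag: int) -> float:
    var = float(np.mean((x - x.mean()) ** 2))
    if var == 0:
        return np.nan
    return lagged_autocovariance(x, lag) / var


def lyapunov_rosenstein(x: np.ndarray, embed_dim: int, delay: int,
                        fit_len: int, theiler: int,
                        samples_per_stride: int) -> float:
    """Largest Lyapunov exponent (per stride) from the divergence curve."""
    x = np.asarray(x, dtype=float)
    emb = _embed(x, embed_dim, delay)
    n = emb.shape[0]
    if n <= fit_len + theiler + 2:
        return np.nan
    dists = cdist(emb, emb)
    idx = np.arange(n)
    band = np.abs(idx[:, None] - idx[None, :]) <= theiler
    dists[band] = np.inf
    # neighbours must leave room for the divergence horizon
    dists[:, n - fit_len:] = np.inf
    usable = idx[:n - fit_len]
    nn = np.argmin(dists[usable], axis=1)
    finite = np.isfinite(dists[usable, nn])
    usable, nn = usable[finite], nn[finite]
    if usable.size == 0:
        return np.nan
    curve = np.empty(fit_len + 1)
    for k in range(fit_len + 1):
        d = np.linalg.norm(emb[usable + k] - emb[nn + k], axis=1)
        good = d > 0
        curve[k] = np.mean(np.log(d[good])) if good.any() else np.nan
    ks = np.arange(fit_len + 1)
    good = np.isfinite(curve)
    if good.sum() < 2:
        return np.nan
    slope = np.polyfit(ks[good], curve[good], 1)[0]
    return float(slope * samples_per_stride)


def time_normalise(x: np.ndarray, contacts: np.ndarray, n_strides: int,
                   samples_per_stride: int) -> np.ndarray:
    """Resample the first ``n_strides`` strides to equal samples per stride."""
    segments = []
    for c0, c1 in zip(contacts[:n_strides], contacts[1:n_strides + 1]):
        seg = x[int(c0):int(c1) + 1]
        src = np.linspace(0.0, 1.0, seg.size)
        dst = np.linspace(0.0, 1.0, samples_per_stride, endpoint=False)
        segments.append(np.interp(dst, src, seg))
    return np.concatenate(segments)


def complexity_features(oriented: Dict[str, OrientedSignal],
                        events_left: Optional[GaitEvents],
                        events_right: Optional[GaitEvents],
                        config: Optional[RunConfig] = None
                        ) -> Tuple[Values, Missing]:
    """All 63 complexity features (3 sensors x 3 axes x 7 measures).

    The low back is anchored to the left-foot stride cycle for time
    normalisation (its own event detection is less dependable and the cycle
    timing is shared).
    """
    cfg = config or RunConfig()
    window = cfg.complexity_window_strides
    sps = cfg.samples_per_stride
    values: Values = {}
    missing: Missing = {}
    references = {"left_foot": events_left, "right_foot": events_right,
                  "low_back": events_left}
    measures = ("sample_entropy", "approximate_entropy", "lyapunov",
                "stride_autocorrelation", "stride_autocovariance",
                "step_autocorrelation", "step_autocovariance")

    for source, sig in oriented.items():
        ref = references.get(source)
        axes = {"vt": sig.accel_vt, "ml": sig.accel_ml, "ap": sig.accel_ap}
        if ref is None:
            reason = "detection_failed"
        elif ref.contact_samples.size < window + 1:
            reason = "insufficient_strides"
        else:
            reason = None
        for axis, x in axes.items():
            if reason is not None:
                for m in measures:
                    missing[f"{source}_{axis}_{m}"] = reason
                continue
            series = time_normalise(x, ref.contact_samples, window, sps)
            r = cfg.entropy_r_factor * series.std()
            values[f"{source}_{axis}_sample_entropy"] = sample_entropy(
                series, cfg.entropy_m, r)
            values[f"{source}_{axis}_approximate_entropy"] = approximate_entropy(
                series, cfg.entropy_m, r)
            values[f"{source}_{axis}_stride_autocorrelation"] = \
                lagged_autocorrelation(series, sps)
            values[f"{source}_{axis}_stride_autocovariance"] = \
                lagged_autocovariance(series, sps)
            values[f"{source}_{axis}_step_autocorrelation"] = \
                lagged_autocorrelation(series, sps // 2)
            values[f"{source}_{axis}_step_autocovariance"] = \
                lagged_autocovariance(series, sps // 2)
            values[f"{source}_{axis}_lyapunov"] = lyapunov_rosenstein(
                series, cfg.lyap_embed_dim,
                max(1, int(round(cfg.lyap_delay_frac * sps))),
                max(2, int(round(cfg.lyap_fit_frac * sps))),
                theiler=sps, samples_per_stride=sps)
    return values, missing
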