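"""Run configuration: every pipeline constant surfaced with its default.

Defaults are the printed values of the processing protocol this package
implements (two-second trims, ten-second length tolerance, 0.75x peak
distance, 1.5x gap factor, 0.2-s minimum stance, 10-stride blocks,
25-stride complexity window). Keeping them in one auditable object makes
them sweepable from the CLI and from YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path
from typing import Tuple

import yaml

from .errors import ValidationError

#: Standard gravity in m/s^2; accelerometer streams are specific force.
GRAVITY = 9.80665


@dataclass
class RunConfig:
    # --- protocol / preprocessing -------------------------------------
    expected_duration_s: float = 120.0   # expected walking duration
    target_rate_hz: float = 100.0        # analysis sample rate after resampling
    trim_s: float = 2.0                  # transitional seconds dropped at each end
    length_tolerance_s: float = 10.0     # strict exclusion bound on length deviation
    stationary_min_s: float = 0.5        # minimum stationary bookend accepted
    stationary_smooth_s: float = 0.25    # magnitude smoothing window for bounds
    # --- stride detection ---------------------------------------------
    peak_distance_factor: float = 0.75   # x average stride time, peak spacing
    gap_factor: float = 1.5              # x average stride time, false-negative gap
    fn_height_factor: float = 0.75       # height rescale in the false-negative pass
    stance_min_s: float = 0.2            # minimum quiescent span counted as stance
    prior_band_hz: Tuple[float, float] = (0.2, 2.5)
    prior_bounds_s: Tuple[float, float] = (0.4, 5.0)
    prior_peak_min_ratio: float = 3.0    # dominant peak vs median spectrum magnitude
    # --- orientation / ZUPT -------------------------------------------
    madgwick_beta: float = 0.1           # gradient-descent gain of the fusion filter
    static_init_s: float = 1.0           # quasi-static lead-in for attitude init
    static_gyro_max_dps: float = 5.0     # gyro norm bound defining "quasi-static"
    # --- low-back events ----------------------------------------------
    lowback_band_hz: Tuple[float, float] = (0.25, 15.0)
    lowback_filter_order: int = 2
    lowback_ap_mode: str = "integrate_once"  # or "integrate_twice"
    snap_tolerance_frac: float = 0.25    # template snap window, fraction of interval
    ml_positive_foot: str = "right"      # foot assigned to positive mean ML accel
    # --- features -------------------------------------------------------
    block_strides: int = 10              # spatio-temporal summarisation block
    complexity_window_strides: int = 25  # fixed stride count for complexity features
    samples_per_stride: int = 100        # time normalisation for complexity features
    min_frequency_span_s: float = 30.0   # minimum walking span for spectral features
    freq_band_hz: Tuple[float, float] = (0.2, 5.0)
    freq_power_fraction: float = 0.5     # power fraction defining dominant width
    welch_segment_s: float = 10.0
    entropy_m: int = 2
    entropy_r_factor: float = 0.2        # tolerance as fraction of series SD
    lyap_embed_dim: int = 5
    lyap_delay_frac: float = 0.25        # embedding delay, fraction of a stride
    lyap_fit_frac: float = 0.5           # divergence-fit span, fraction of a stride
    # --- misc -----------------------------------------------------------
    seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "expected_duration_s", "target_rate_hz", "trim_s",
            "length_tolerance_s", "stationary_min_s", "stationary_smooth_s",
            "peak_distance_factor", "gap_factor", "fn_height_factor",
            "stance_min_s", "prior_peak_min_ratio", "madgwick_beta",
            "static_init_s", "static_gyro_max_dps", "snap_tolerance_frac",
            "block_strides", "complexity_window_strides", "samples_per_stride",
            "min_frequency_span_s", "freq_power_fraction", "welch_segment_s",
            "entropy_m", "entropy_r_factor", "lyap_embed_dim",
            "lyap_delay_frac", "lyap_fit_frac", "lowback_filter_order",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValidationError(name, "must be positive")
        if self.lowback_ap_mode not in ("integrate_once", "integrate_twice"):
            raise ValidationError("lowback_ap_mode", "unknown mode")
        if self.ml_positive_foot not in ("left", "right"):
            raise ValidationError("ml_positive_foot", "must be 'left' or 'right'")
        for name in ("prior_band_hz", "prior_bounds_s", "lowback_band_hz",
                     "freq_band_hz"):
            lo, hi = getattr(self, name)
            if not 0 < lo < hi:
                raise ValidationError(name, "must be an increasing positive pair")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(sorted(unknown)[0], "unknown config key")
        for key in ("prior_band_hz", "prior_bounds_s", "lowback_band_hz",
                    "freq_band_hz"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
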