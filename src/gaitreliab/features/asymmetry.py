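"""Between-foot asymmetry features referenced to the paretic side.

For each quantity Q (swing time, stance time, stride time, step time,
stride length, stride velocity, swing/stance ratio), with P the paretic-side
mean and NP the non-paretic mean:

    SI    = |P - NP| / (0.5 * (P + NP)) * 100      (symmetry index, %)
    ratio = P / NP                                  (symmetry ratio)

When the paretic side is undefined (unknown, or both sides affected) the
left foot is used as the reference.
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np

from ..config import RunConfig
from ..io_preprocess import SubjectMeta
from ..orientation import StrideDisplacement
from ..stride_detection import GaitEvents
from .catalogue import ASYMMETRY_QUANTITIES
from .spatio_temporal import block_stats, foot_series

Values = Dict[str, float]
Missing = Dict[str, str]


def reference_foot(meta: SubjectMeta) -> str:
    """Paretic reference foot; left-foot fallback when undefined."""
    if meta.paretic_side in ("left", "right"):
        return meta.paretic_side
    return "left"


def symmetry_index(p: float, np_: float) -> float:
    denom = 0.5 * (p + np_)
    if denom == 0:
        return np.nan
    return abs(p - np_) / denom * 100.0


def _foot_quantities(events: GaitEvents, other: GaitEvents,
                     disp: Optional[StrideDisplacement],
                     block: int) -> Dict[str, float]:
    series = foot_series(events, other,
                         disp.lengths if disp is not None else None)
    out: Dict[str, float] = {}
    for name, values in series.items():
        stats = block_stats(values, block)
        if stats is not None:
            out[name] = stats[0]
    if "swing_time" in out and "stance_time" in out and out["stance_time"] > 0:
        out["swing_stance_ratio"] = out["swing_time"] / out["stance_time"]
    return out


def asymmetry_features(events_left: Optional[GaitEvents],
                       events_right: Optional[GaitEvents],
                       displacements: Dict[str, Optional[StrideDisplacement]],
                       meta: SubjectMeta,
                       config: Optional[RunConfig] = None
                       ) -> Tuple[Values, Missing]:
    """All 14 asymmetry features (7 quantities x SI and ratio)."""
    cfg = config or RunConfig()
    values: Values = {}
    missing: Missing = {}
    names = [f"combined_{q}_{s}" for q in ASYMMETRY_QUANTITIES
             for s in ("si", "ratio")]
    if events_left is None or events_right is None:
        for name in names:
            missing[name] = "detection_failed"
        return values, missing

    ref = reference_foot(meta)
    feet = {
        "left": _foot_quantities(events_left, events_right,
                                 displacements.get("left_foot"),
                                 cfg.block_strides),
        "right": _foot_quantities(events_right, events_left,
                                  displacements.get("right_foot"),
                                  cfg.block_strides),
    }
    paretic = feet[ref]
    nonparetic = feet["right" if ref == "left" else "left"]
    for quantity in ASYMMETRY_QUANTITIES:
        si_name = f"combined_{quantity}_si"
        ratio_name = f"combined_{quantity}_ratio"
        if quantity not in paretic or quantity not in nonparetic:
            missing[si_name] = "insufficient_strides"
            missing[ratio_name] = "insufficient_strides"
            continue
        p, np_ = paretic[quantity], nonparetic[quantity]
        values[si_name] = symmetry_index(p, np_)
        if np_ == 0:
            missing[ratio_name] = "zero_reference"
        else:
            values[ratio_name] = p / np_
    return values, missing
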