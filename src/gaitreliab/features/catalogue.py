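"""The versioned 166-feature gait catalogue.

Four named domains carry 56 spatio-temporal, 26 frequency, 63 complexity and
14 asymmetry features; a small fifth domain of low-back signal-magnitude
features closes the catalogue at 166. Per sensor the catalogue holds 46
left-foot, 46 right-foot and 54 low-back features, with the remaining 20
computed from combined sources (the 14 asymmetry features plus 6 bilateral
spatio-temporal ones). The catalogue ships as a JSON manifest
(``data/feature_manifest.json``) and is rebuilt programmatically here; a
consistency test keeps the two in lockstep.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional

from ..errors import CatalogueError

CATALOGUE_VERSION = "1.0"

DOMAINS = ("spatio_temporal", "frequency", "complexity", "asymmetry",
           "signal_magnitude")
SOURCES = ("left_foot", "right_foot", "low_back", "combined")

#: expected per-domain counts of the four named domains
DOMAIN_COUNTS = {"spatio_temporal": 56, "frequency": 26, "complexity": 63,
                 "asymmetry": 14, "signal_magnitude": 7}
SOURCE_COUNTS = {"left_foot": 46, "right_foot": 46, "low_back": 54,
                 "combined": 20}
TOTAL_FEATURES = 166

AXES = ("vt", "ml", "ap")

COMPLEXITY_MEASURES = (
    ("sample_entropy", "-"),
    ("approximate_entropy", "-"),
    ("lyapunov", "1/stride"),
    ("stride_autocorrelation", "-"),
    ("stride_autocovariance", "(m/s^2)^2"),
    ("step_autocorrelation", "-"),
    ("step_autocovariance", "(m/s^2)^2"),
)

ASYMMETRY_QUANTITIES = (
    "swing_time", "stance_time", "stride_time", "step_time",
    "stride_length", "stride_velocity", "swing_stance_ratio",
)


@dataclass(frozen=True)
class FeatureDef:
    name: str
    domain: str
    source: str
    units: str
    normalisation: str = "none"   # none | height | paretic_reference

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise CatalogueError(f"unknown domain {self.domain!r}")
        if self.source not in SOURCES:
            raise CatalogueError(f"unknown source {self.source!r}")


def _foot_features(source: str) -> List[FeatureDef]:
    defs: List[FeatureDef] = []
    st = [("stride_time", "s"), ("stance_time", "s"), ("swing_time", "s"),
          ("step_time", "s"), ("stride_length", "m"), ("stride_velocity", "m/s")]
    for base, unit in st:
        for stat, u in (("mean", unit), ("sd", unit), ("cv", "%")):
            defs.append(FeatureDef(f"{source}_{base}_{stat}", "spatio_temporal",
                                   source, u))
    defs.append(FeatureDef(f"{source}_cadence", "spatio_temporal", source,
                           "steps/min"))
    defs.append(FeatureDef(f"{source}_stride_length_height_norm",
                           "spatio_temporal", source, "-", "height"))
    defs.append(FeatureDef(f"{source}_stride_velocity_height_norm",
                           "spatio_temporal", source, "1/s", "height"))
    for base, unit in (("dominant_frequency", "Hz"),
                       ("dominant_amplitude", "m/s^2"),
                       ("dominant_width", "Hz"),
                       ("dominant_density", "-")):
        defs.append(FeatureDef(f"{source}_vt_{base}", "frequency", source, unit))
    for axis in AXES:
        for base, unit in COMPLEXITY_MEASURES:
            defs.append(FeatureDef(f"{source}_{axis}_{base}", "complexity",
                                   source, unit))
    return defs


def _lowback_features() -> List[FeatureDef]:
    src = "low_back"
    defs: List[FeatureDef] = []
    for base in ("stride_time", "step_time"):
        for stat, u in (("mean", "s"), ("sd", "s"), ("cv", "%")):
            defs.append(FeatureDef(f"{src}_{base}_{stat}", "spatio_temporal",
                                   src, u))
    defs.append(FeatureDef(f"{src}_cadence", "spatio_temporal", src, "steps/min"))
    defs.append(FeatureDef(f"{src}_stride_time_range", "spatio_temporal", src, "s"))
    for axis in AXES:
        for base, unit in (("dominant_frequency", "Hz"),
                           ("dominant_amplitude", "m/s^2"),
                           ("dominant_width", "Hz"),
                           ("dominant_density", "-"),
                           ("harmonicity_index", "-"),
                           ("harmonic_ratio", "-")):
            defs.append(FeatureDef(f"{src}_{axis}_{base}", "frequency", src, unit))
    for axis in AXES:
        for base, unit in COMPLEXITY_MEASURES:
            defs.append(FeatureDef(f"{src}_{axis}_{base}", "complexity", src, unit))
    for axis in AXES:
        defs.append(FeatureDef(f"{src}_{axis}_rms", "signal_magnitude", src,
                               "m/s^2"))
    for axis in AXES:
        defs.append(FeatureDef(f"{src}_{axis}_range", "signal_magnitude", src,
                               "m/s^2"))
    defs.append(FeatureDef(f"{src}_rms_total", "signal_magnitude", src, "m/s^2"))
    return defs


def _combined_features() -> List[FeatureDef]:
    src = "combined"
    defs = [
        FeatureDef(f"{src}_gait_speed", "spatio_temporal", src, "m/s"),
        FeatureDef(f"{src}_gait_speed_height_norm", "spatio_temporal", src,
                   "1/s", "height"),
        FeatureDef(f"{src}_stride_time_bilateral_mean", "spatio_temporal", src, "s"),
        FeatureDef(f"{src}_stride_length_bilateral_mean", "spatio_temporal",
                   src, "m"),
        FeatureDef(f"{src}_stride_length_bilateral_height_norm",
                   "spatio_temporal", src, "-", "height"),
        FeatureDef(f"{src}_double_support_time_mean", "spatio_temporal", src, "s"),
    ]
    for quantity in ASYMMETRY_QUANTITIES:
        defs.append(FeatureDef(f"{src}_{quantity}_si", "asymmetry", src, "%",
                               "paretic_reference"))
        defs.append(FeatureDef(f"{src}_{quantity}_ratio", "asymmetry", src, "-",
                               "paretic_reference"))
    return defs


def build_catalogue() -> List[FeatureDef]:
    """Construct the catalogue programmatically and verify its invariants."""
    defs = (_foot_features("left_foot") + _foot_features("right_foot")
            + _lowback_features() + _combined_features())
    validate_catalogue(defs)
    return defs


def validate_catalogue(defs: List[FeatureDef]) -> None:
    names = [d.name for d in defs]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise CatalogueError(f"duplicate feature names: {dupes}")
    if len(defs) != TOTAL_FEATURES:
        raise CatalogueError(f"catalogue has {len(defs)} features, "
                             f"expected {TOTAL_FEATURES}")
    for domain, expected in DOMAIN_COUNTS.items():
        got = sum(d.domain == domain for d in defs)
        if got != expected:
            raise CatalogueError(f"domain {domain}: {got} != {expected}")
    for source, expected in SOURCE_COUNTS.items():
        got = sum(d.source == source for d in defs)
        if got != expected:
            raise CatalogueError(f"source {source}: {got} != {expected}")


def export_manifest(path: str | Path,
                    defs: Optional[List[FeatureDef]] = None) -> None:
    defs = defs or build_catalogue()
    payload = {"version": CATALOGUE_VERSION,
               "features": [asdict(d) for d in defs]}
    Path(path).write_text(json.dumps(payload, indent=1))


def load_manifest(path: Optional[str | Path] = None) -> List[FeatureDef]:
    """Load the shipped (or an external) JSON manifest."""
    if path is None:
        text = (resources.files("gaitreliab") / "data" /
                "feature_manifest.json").read_text()
    else:
        text = Path(path).read_text()
    payload = json.loads(text)
    defs = [FeatureDef(**d) for d in payload["features"]]
    validate_catalogue(defs)
    return defs


def catalogue_index(defs: List[FeatureDef]) -> Dict[str, FeatureDef]:
    return {d.name: d for d in defs}
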