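"""Assembly of partial feature maps into one validated 166-key vector."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from ..errors import CatalogueError
from .catalogue import FeatureDef, build_catalogue

Partial = Tuple[Dict[str, float], Dict[str, str]]


@dataclass
class FeatureVector:
    """One assessment's named feature values with missing-reason codes."""

    assessment_id: str
    values: Dict[str, float]
    missing: Dict[str, str] = field(default_factory=dict)
    strides_used: Dict[str, int] = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return len(self.values)

    @property
    def n_missing(self) -> int:
        return len(self.missing)

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, name=self.assessment_id)

    def to_frame(self) -> pd.DataFrame:
        df = self.to_series().to_frame().T
        df.insert(0, "assessment_id", self.assessment_id)
        return df


def assemble(partials: List[Partial],
             catalogue: Optional[List[FeatureDef]] = None,
             assessment_id: str = "assessment",
             strides_used: Optional[Dict[str, int]] = None) -> FeatureVector:
    """Merge partial feature maps; enforce exact catalogue key coverage."""
    defs = catalogue or build_catalogue()
    names = {d.name for d in defs}
    values: Dict[str, float] = {}
    missing: Dict[str, str] = {}
    for vals, miss in partials:
        overlap = set(vals) & set(values)
        if overlap:
            raise CatalogueError(f"duplicate feature keys across partials: "
                                 f"{sorted(overlap)[:5]}")
        unknown = (set(vals) | set(miss)) - names
        if unknown:
            raise CatalogueError(f"keys not in the catalogue: "
                                 f"{sorted(unknown)[:5]}")
        values.update(vals)
        missing.update(miss)
    for name in names:
        if name not in values and name not in missing:
            missing[name] = "not_computed"
    ordered = {d.name: values.get(d.name, np.nan) for d in defs}
    missing = {k: v for k, v in missing.items() if k not in values}
    return FeatureVector(assessment_id=assessment_id, values=ordered,
                         missing=missing, strides_used=strides_used or {})
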