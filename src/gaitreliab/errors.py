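"""Exception hierarchy for the gait-assessment pipeline.

Every failure mode that maps to a documented exclusion or repair rule raises
a dedicated subclass so callers (and the CLI) can report the triggering rule
by name.
"""


class GaitError(Exception):
    """Base class for all pipeline errors."""


class ValidationError(GaitError, ValueError):
    """A specification or configuration field is invalid; names the field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class CalibrationError(GaitError):
    """Gyroscope bias calibration failed (motion detected in the recording)."""


class PreprocessError(GaitError):
    """Preprocessing could not locate a usable walking period."""


class OrientationError(GaitError):
    """Sensor-fusion initialisation failed (no quasi-static lead-in)."""


class PriorEstimationError(GaitError):
    """No dominant stride frequency could be found in the ML acceleration."""


class DetectionError(GaitError):
    """Stride detection failed for a foot (no stance phase anywhere)."""


class LowBackDetectionError(GaitError):
    """Low-back event detection failed (non-fatal: features marked missing)."""


class CatalogueError(GaitError):
    """Feature-catalogue consistency violation (key/manifest mismatch)."""


class ReliabilityError(GaitError):
    """Reliability statistics could not be computed (e.g. too few subjects)."""
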