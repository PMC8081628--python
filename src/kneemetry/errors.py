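"""Exception hierarchy for the measurement pipeline.

Pipeline stages raise typed errors so the orchestrator can record the exact
failure stage in the Report and drive the Canny parameter-group retry.
"""


class KneemetryError(Exception):
    """Base class for all package errors."""


class ValidationError(KneemetryError, ValueError):
    """Invalid argument or specification; message names the violated rule."""


class FormatError(KneemetryError, IOError):
    """Unreadable or unsupported image file."""


class DetectionFailure(KneemetryError):
    """The joint region of interest could not be located."""


class LandmarkFailure(KneemetryError):
    """A landmark stage failed; ``stage`` is one of
    pofb / condyles / spines / plateau / baseline."""

    def __init__(self, stage: str, message: str = ""):
        self.stage = stage
        super().__init__(message or f"landmark failure at stage '{stage}'")


class MeasurementFailure(KneemetryError):
    """All Canny parameter groups were exhausted without a full landmark set."""

    def __init__(self, last_stage: str, message: str = ""):
        self.last_stage = last_stage
        super().__init__(message or f"measurement failed; last stage: '{last_stage}'")


class DegenerateMeasurementError(KneemetryError):
    """The landmark geometry yields a numerically meaningless measurement."""
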