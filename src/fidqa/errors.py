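"""Exception hierarchy.

Every failure mode of the pipeline maps to a distinct exception type so the
orchestrator can abort fail-fast with a machine-readable stage/code pair.
"""

from __future__ import annotations


class FidqaError(Exception):
    """Base class for all package errors."""

    code = "error"


class InvalidParameterError(FidqaError, ValueError):
    """A configuration or function parameter violates its documented range."""

    code = "invalid-parameter"


class InvalidMeasurementError(FidqaError, ValueError):
    """A supplied measurement (e.g. a landmark distance) is unusable."""

    code = "invalid-measurement"


class UnsupportedFormatError(FidqaError):
    """Input image file is multi-frame, colour, or otherwise unsupported."""

    code = "unsupported-format"


class MissingSpacingError(FidqaError):
    """A reference image arrived without pixel spacing and no override."""

    code = "missing-spacing"


class GenerationError(FidqaError):
    """Phantom content would fall outside the raster."""

    code = "generation"


class DegenerateHistogramError(FidqaError):
    """Otsu thresholding received a (near-)constant intensity sample."""

    code = "degenerate-histogram"


class DetectionCountError(FidqaError):
    """Number of surviving marker blobs differs from the expected count."""

    code = "detection-count"

    def __init__(self, found: int, expected: int, areas: list[int]):
        self.found = found
        self.expected = expected
        self.areas = list(areas)
        super().__init__(
            f"found {found} candidate marker(s), expected {expected}; "
            f"surviving blob areas (px): {self.areas}"
        )


class UnderdeterminedError(FidqaError):
    """Rigid fit attempted on coincident / insufficient points."""

    code = "underdetermined"


class RasterSizeError(FidqaError):
    """Resampling would produce a raster above the configured maximum."""

    code = "raster-size"


class StageError(FidqaError):
    """Wraps any error raised inside a named pipeline stage."""

    def __init__(self, stage: str, error: Exception):
        self.stage = stage
        self.error = error
        self.code = getattr(error, "code", "error")
        super().__init__(f"stage '{stage}' failed [{self.code}]: {error}")
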