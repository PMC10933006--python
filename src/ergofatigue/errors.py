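"""Exception hierarchy.

ValidationError covers malformed specs/configs/containers (CLI exit code 1);
ProcessingError covers failures inside pipeline stages (exit code 2).
"""


class ErgoFatigueError(Exception):
    """Base class for all package errors."""


class ValidationError(ErgoFatigueError, ValueError):
    """Invalid input, configuration, or container state."""


class ProcessingError(ErgoFatigueError, RuntimeError):
    """A pipeline stage failed on otherwise well-formed input."""


class FormatError(ValidationError):
    """A file did not conform to the expected on-disk format."""


class GeometryError(ProcessingError):
    """Limb geometry and marker distance violate the triangle inequality."""


class SegmentationError(ProcessingError):
    """Cycle-boundary detection could not find enough minima."""


class DecompositionError(ProcessingError):
    """Segment too short for the requested wavelet depth, or similar."""


class InsufficientDataError(ProcessingError):
    """Too few observations for the requested statistic."""
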