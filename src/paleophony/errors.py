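"""Exception hierarchy.

Every error raised by the library derives from :class:`PaleophonyError`, so
callers (and the CLI) can catch one type and report a category string.
"""


class PaleophonyError(ValueError):
    """Base class for all library errors."""

    category = "error"


class InvalidCalibrationError(PaleophonyError):
    """Scale-bar calibration with a non-positive pixel or length value."""

    category = "invalid-calibration"


class DegeneratePathError(PaleophonyError):
    """Polyline with fewer than two points."""

    category = "degenerate-path"


class InvalidPathwayError(PaleophonyError):
    """Airway pathway with missing/unknown metadata or non-positive length."""

    category = "invalid-pathway"


class AcousticsError(PaleophonyError):
    """Invalid acoustic parameters (length, speed of sound, harmonic level)."""

    category = "acoustics"


class InsufficientSampleError(PaleophonyError):
    """Too few observations for a two-sample test."""

    category = "insufficient-sample"


class MatrixFormatError(PaleophonyError):
    """Malformed NEXUS/TNT character matrix."""

    category = "matrix-format"


class TreeMatrixMismatchError(PaleophonyError):
    """Tree leaf labels do not resolve against the character matrix taxa."""

    category = "tree-matrix-mismatch"


class ConfigError(PaleophonyError):
    """Invalid simulation or run configuration."""

    category = "config"
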