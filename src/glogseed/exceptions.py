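"""Exception hierarchy for glogseed."""


class GlogSeedError(Exception):
    """Base class for all glogseed errors."""


class ImageFormatError(GlogSeedError):
    """Raised for unreadable or unsupported image files."""


class ParameterError(GlogSeedError, ValueError):
    """Raised for invalid kernel / config parameters."""


class DimensionError(GlogSeedError, ValueError):
    """Raised when image / kernel / map dimensions are incompatible."""


class PreconditionError(GlogSeedError, ValueError):
    """Raised when an algorithmic precondition (e.g. marker <= mask) is violated."""


class QuantizationOverflowError(GlogSeedError, OverflowError):
    """Raised when a coefficient does not fit the fixed-point integer range."""


class DegenerateHistogramError(GlogSeedError, ValueError):
    """Raised when Otsu thresholding is attempted on a constant image."""


class PlacementError(GlogSeedError, RuntimeError):
    """Raised when synthetic nuclei cannot be placed at the requested separation."""
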