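"""Exception types shared across the package."""


class CytonucleiError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CytonucleiError, ValueError):
    """An image does not have the expected layout (channels, dtype, shape)."""


class DegenerateHistogramError(CytonucleiError, ValueError):
    """A histogram (or image) has too little intensity structure to threshold/cluster."""


class DegenerateInputError(CytonucleiError, ValueError):
    """An image is constant (or nearly so) where distinct classes are required."""


class PlacementError(CytonucleiError, RuntimeError):
    """Nuclei could not be placed without overlap within the retry budget."""


class InitializationError(CytonucleiError, ValueError):
    """A contour/level-set initialization is empty or unusable."""


class AnnotationError(CytonucleiError, KeyError):
    """Ground-truth labels and per-nucleus metadata disagree."""
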