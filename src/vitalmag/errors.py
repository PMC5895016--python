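"""Exception hierarchy for the vitalmag toolkit.

All toolkit errors derive from :class:`VitalmagError` so callers (and the
CLI) can catch one base class; each subclass also derives from the closest
built-in so library users get conventional semantics.
"""


class VitalmagError(Exception):
    """Base class for all vitalmag errors."""


class ConfigurationError(VitalmagError, ValueError):
    """Invalid run configuration (frequencies, alpha, Nyquist violations)."""


class FormatError(VitalmagError, ValueError):
    """Unreadable or malformed video / frame-sequence input."""


class DimensionError(VitalmagError, ValueError):
    """Array shapes incompatible with the requested operation."""


class StructureError(VitalmagError, ValueError):
    """Mismatched pyramid / decomposition structure."""


class DegenerateInputError(VitalmagError, ValueError):
    """Input carries no usable signal (e.g. textureless ROI)."""
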