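"""Exception hierarchy used across the package."""


class CytoError(Exception):
    """Base class for all package errors."""


class FormatError(CytoError):
    """A file could not be parsed as the requested format."""


class PanelError(CytoError):
    """Channel panel inconsistency (duplicates, missing channels, ...)."""


class ParameterError(CytoError, ValueError):
    """An operation received an invalid parameter value."""


class DesignError(CytoError):
    """A synthetic study design violates its invariants."""


class AssemblyError(CytoError):
    """Dataset assembly produced an empty or inconsistent result."""


class PeakDetectionError(CytoError):
    """Control peak detection failed."""


class UnimodalError(PeakDetectionError):
    """Fewer than two density modes were found in a bead channel."""


class AmbiguousPeaksError(PeakDetectionError):
    """The two dominant modes are too close to separate reliably."""


class DegenerateControlError(CytoError):
    """Control peaks coincide; the two-point model is undefined."""


class TooFewEventsError(CytoError):
    """Not enough events for the requested operation."""
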