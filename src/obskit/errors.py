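"""Exception hierarchy shared across the toolkit."""


class OBSError(Exception):
    """Base class for all toolkit errors."""


class FormatError(OBSError):
    """A file or container does not conform to the expected layout."""


class GeometryError(OBSError):
    """Array geometry is inconsistent, degenerate, or mismatched with data."""


class UsageError(OBSError):
    """An operation was invoked with invalid options or arguments."""


class ValidationError(OBSError):
    """A domain object violates its invariants."""


class ConfigurationError(OBSError):
    """Reconstruction or simulation configuration cannot be realized."""


class MeasurementError(OBSError):
    """A metric is undefined on the given input (e.g. no threshold crossing)."""


class FitError(OBSError):
    """A model fit is degenerate or failed diagnostics."""
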