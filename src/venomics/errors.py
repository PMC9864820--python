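"""Exception hierarchy shared across the pipeline stages."""


class VenomicsError(Exception):
    """Base class for all package errors."""


class ConfigurationError(VenomicsError, ValueError):
    """A configuration value violates its contract (bad weights, negative counts...)."""


class ValidationError(VenomicsError, ValueError):
    """Input data violates a structural invariant (duplicate ids, non-finite values...)."""


class ParseError(VenomicsError, ValueError):
    """A run file could not be parsed under the named format."""


class UnsupportedModeError(ParseError):
    """Profile-mode spectra were supplied to a centroid-only pipeline."""


class GroupingError(VenomicsError, ValueError):
    """A sample grouping is unusable (fewer than two groups)."""
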