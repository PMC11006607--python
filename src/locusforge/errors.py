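"""Exception types shared across the package."""


class LocusForgeError(Exception):
    """Base class for all package-specific errors."""


class FormatError(LocusForgeError, ValueError):
    """A file did not conform to its declared text format."""


class ParameterError(LocusForgeError, ValueError):
    """An argument violates an operation's preconditions."""


class BoundsError(LocusForgeError, ValueError):
    """A coordinate or region falls outside the available sequence/track."""


class InsufficientDataError(LocusForgeError, ValueError):
    """Too few data points survive filtering for the statistic to be defined."""
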