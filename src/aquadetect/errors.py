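"""Exception hierarchy shared across the pipeline stages."""


class AquadetectError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(AquadetectError, ValueError):
    """A caller-supplied parameter is outside its valid domain."""


class DataError(AquadetectError, ValueError):
    """Input data violates a structural precondition (bounds, lengths, ids)."""


class MemberLookupError(AquadetectError, KeyError):
    """A referenced genome/contig/taxon id cannot be resolved."""


class FitError(AquadetectError, RuntimeError):
    """Nonlinear fit failed to converge or the series is degenerate.

    Carries diagnostics in ``details``.
    """

    def __init__(self, message: str, details: dict | None = None):
        super().__init__(message)
        self.details = details or {}


class SaturationError(AquadetectError, ValueError):
    """A distance correction is undefined (log/power argument <= 0)."""


class RootingError(AquadetectError, ValueError):
    """A tree cannot be midpoint-rooted (e.g. all branch lengths zero)."""
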