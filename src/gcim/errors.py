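"""Exception taxonomy shared across the package."""


class GcimError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(GcimError):
    """Invalid simulation or analysis configuration (bad bounds, non-PSD matrix, ...)."""


class ContractError(GcimError):
    """Caller violated an interface contract (mismatched shapes, bad fractions, ...)."""


class DegenerateInputError(GcimError):
    """Input is formally valid but statistically degenerate (constant vector, ...)."""


class CollinearityError(GcimError):
    """Model design matrix is rank deficient."""

    def __init__(self, aliased, message=None):
        self.aliased = list(aliased)
        super().__init__(message or f"design matrix is rank deficient; aliased columns: {self.aliased}")


class FormatError(GcimError):
    """A file on disk does not conform to its declared format."""


class AnalysisError(GcimError):
    """An analysis step failed in a way that invalidates the result."""
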