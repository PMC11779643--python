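"""Exception hierarchy shared across the package."""


class RegionSigError(Exception):
    """Base class for all package errors."""


class ValidationError(RegionSigError):
    """Raised when an input object violates its declared invariants."""


class CoverageError(RegionSigError):
    """Raised when too few signature genes are present in a cohort."""

    def __init__(self, message: str, missing_genes=()):
        super().__init__(message)
        self.missing_genes = tuple(missing_genes)


class ConvergenceError(RegionSigError):
    """Raised when an iterative fit fails to converge."""
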