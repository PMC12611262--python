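"""Exception and warning types shared across the package."""


class OtoError(Exception):
    """Base class for all package-specific errors."""


class FormatError(OtoError):
    """A file does not conform to its declared grammar."""


class IntegrityError(OtoError):
    """A file parses but its numeric content is internally inconsistent."""


class AlignmentError(OtoError):
    """Genomic intervals do not line up with the expected bin grid."""


class ConfigError(OtoError):
    """A simulation or analysis configuration is invalid."""


class UsageError(OtoError):
    """An operation was called on inputs in the wrong state."""


class DegenerateInputError(OtoError):
    """Numerically degenerate input (constant columns, zero variance, ...)."""


class ConvergenceWarning(UserWarning):
    """An iterative procedure stopped at its iteration cap."""


class OrientationWarning(UserWarning):
    """Track orientation is ambiguous (weak covariate correlation)."""
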