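"""Exception hierarchy shared across the package."""


class SomaQtlError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(SomaQtlError, ValueError):
    """An invalid configuration value (e.g. a MAF range outside [0.05, 0.5])."""


class AlignmentError(SomaQtlError, ValueError):
    """Sample or variant identifiers do not line up between two tables."""


class StateError(SomaQtlError, RuntimeError):
    """An operation was called before its prerequisites were computed."""


class DesignError(SomaQtlError, ValueError):
    """A regression design matrix is rank deficient or confounded."""
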