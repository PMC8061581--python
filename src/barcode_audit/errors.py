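"""Exception hierarchy for the audit pipeline."""


class AuditError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(AuditError):
    """Invalid configuration: missing metadata columns, bad parameter values."""


class DataError(AuditError):
    """Malformed input data: duplicate ids, illegal characters, bad offsets."""


class UndefinedDistanceError(AuditError):
    """Too few pairwise-complete sites to report a distance."""


class SaturationError(AuditError):
    """K2P logarithm argument non-positive: divergence beyond correctable range."""
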