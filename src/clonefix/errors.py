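"""Exception types shared across the package."""


class ClonefixError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(ClonefixError, ValueError):
    """A model or generator parameter violates its contract."""


class UndefinedRateError(ClonefixError, ValueError):
    """A growth rate cannot be computed (zero/negative endpoint count)."""


class ConditionMismatchError(ClonefixError, ValueError):
    """A fitness ratio was requested across mismatched culture conditions."""


class SchemaError(ClonefixError, ValueError):
    """A table does not conform to the expected column schema or constraints."""


class ConfigError(ClonefixError, ValueError):
    """A configuration file contains unknown or invalid keys."""
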