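"""Exception hierarchy shared across the package."""


class SimlabelError(Exception):
    """Base class for all package errors."""


class ValidationError(SimlabelError):
    """A configuration object (grouping, manifest, schedule, ...) violates its contract."""


class DimensionError(SimlabelError):
    """Array shapes or label-space dimensions do not agree."""


class DataError(SimlabelError):
    """Input data (mask values, colors, probabilities) is out of contract."""


class ConfigurationError(SimlabelError):
    """A run was configured in a way the method cannot execute."""


class DegenerateInputError(SimlabelError):
    """Statistically degenerate input (e.g. identical paired samples)."""
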