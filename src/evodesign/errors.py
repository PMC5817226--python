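"""Exception hierarchy shared across the package."""


class EvodesignError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(EvodesignError):
    """Invalid design configuration (factors, objectives, GA parameters)."""


class DataError(EvodesignError):
    """Malformed or unrepairable measurement data."""


class StateError(EvodesignError):
    """An operation was requested in the wrong session state."""
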