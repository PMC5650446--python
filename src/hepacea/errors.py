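"""Exception types shared across the package."""


class HepaceaError(Exception):
    """Base class for all package errors."""


class ParameterError(HepaceaError, ValueError):
    """A model parameter violates its domain (range, sign, finiteness)."""


class ConfigError(HepaceaError, ValueError):
    """A run configuration references unknown parameters or invalid settings."""


class MedianNotReachedError(HepaceaError):
    """Survival never falls below 50% within the modeled horizon."""
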