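"""Exception hierarchy shared across the pipeline."""


class PreclinPKError(Exception):
    """Base class for all package errors."""


class SchemaError(PreclinPKError):
    """An input table is missing a required column or has a malformed layout."""


class ValidationError(PreclinPKError):
    """A record violates a structural invariant (e.g. duplicate times)."""


class InsufficientDataError(PreclinPKError):
    """Too few usable observations for the requested computation."""


class NoTerminalPhaseError(PreclinPKError):
    """No candidate terminal window has a negative log-linear slope."""


class DomainError(PreclinPKError):
    """A numeric argument is outside the mathematically valid domain."""


class LookupError_(PreclinPKError):
    """Unknown species or organ requested from a registry."""


class ConstructionError(PreclinPKError):
    """A model specification is internally inconsistent (e.g. flow topology)."""


class PairingError(PreclinPKError):
    """Predicted and observed scenarios could not be matched."""


class ConfigError(PreclinPKError):
    """A generator or run configuration is invalid."""
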