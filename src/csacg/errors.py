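"""Exception hierarchy."""


class CsacgError(Exception):
    """Base class for all package errors."""


class DomainError(CsacgError, ValueError):
    """An argument is outside the physically meaningful domain."""


class ConfigurationError(CsacgError):
    """Template or configuration data is missing or inconsistent."""


class ValidationError(CsacgError):
    """Internal consistency check of a built object failed."""


class MappingError(CsacgError):
    """Atom referenced by a mapping table is absent from the input."""


class PairingError(CsacgError):
    """Reference and model term lists cannot be aligned."""


class FitError(CsacgError):
    """A fit has too little data or is otherwise ill-posed."""
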