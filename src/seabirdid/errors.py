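"""Exception hierarchy shared across the package."""


class SeabirdIdError(Exception):
    """Base class for all package errors."""


class ValidationError(SeabirdIdError):
    """Input content violates a documented invariant (CLI exit code 1)."""


class InputError(SeabirdIdError):
    """A required file or path is missing or unreadable (CLI exit code 2)."""


class UnalignableQueryError(SeabirdIdError):
    """A query cannot be placed on the reference alignment."""
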