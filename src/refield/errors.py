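"""Exception types shared across the package."""


class RefieldError(Exception):
    """Base class for package errors."""


class ValidationError(RefieldError, ValueError):
    """Raised when inputs violate a documented precondition."""
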