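"""Exception types shared across the package."""


class SSBSimError(ValueError):
    """Base class for validation and configuration failures."""


class ConfigurationError(SSBSimError):
    """A configuration table is incomplete or structurally wrong."""


class ValidationError(SSBSimError):
    """A supplied value violates a documented precondition or invariant."""
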