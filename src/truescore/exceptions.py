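"""Exception types shared across the package."""


class InvalidInputError(ValueError):
    """Raised when user-supplied data violate a precondition."""


class ConfigurationError(ValueError):
    """Raised when an analysis configuration is internally inconsistent,
    e.g. a sample-size adjustment is requested for a typical error whose
    provenance carries no degrees of freedom."""
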