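"""Exception types shared across the pipeline."""


class ConfigurationError(ValueError):
    """A simulation or pipeline configuration field is invalid.

    The message always names the offending field.
    """


class DomainError(ValueError):
    """An input is outside the physical domain of an operation
    (negative diameter, zero sample volume, rock volume exceeding
    sample volume, ...)."""
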