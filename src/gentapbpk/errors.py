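"""Error types shared across the package."""


class ConfigurationError(ValueError):
    """A configuration value or key is invalid (unknown organ, stage, key...)."""


class NumericalError(RuntimeError):
    """The numerical machinery failed (solver non-convergence, negative state)."""
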