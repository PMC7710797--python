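class ConfigurationError(ValueError):
    """A required column, option, or parameter is missing or malformed."""


class DataError(ValueError):
    """Input data cannot support the requested analysis."""


class EstimationError(RuntimeError):
    """A numerical routine failed to converge; carries diagnostics in args."""
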