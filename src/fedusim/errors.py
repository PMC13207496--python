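"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A configuration value violates a precondition; the message names the field."""


class PipelineError(RuntimeError):
    """A processing stage produced invalid output; the message names the stage."""
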