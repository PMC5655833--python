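"""Exception types shared across the pipeline."""


class ConfigError(ValueError):
    """A configuration field is invalid; the message names the field."""


class SchemaError(ValueError):
    """An input table does not conform to the expected schema."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""
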