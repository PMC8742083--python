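"""Exception types shared across the pipeline."""


class ConfigurationError(ValueError):
    """A configuration value is invalid; the message names the offending field."""


class SchemaError(ValueError):
    """A feature schema references a source that cannot be resolved."""


class ParseError(ValueError):
    """An input file is malformed; the message carries file/column context."""
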