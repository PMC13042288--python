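class MalinesError(Exception):
    """Base class for package errors."""


class ParseError(MalinesError):
    """A file violated its documented dialect."""


class ConfigurationError(MalinesError):
    """Inputs are individually valid but mutually inconsistent."""
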