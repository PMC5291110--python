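"""Exception hierarchy shared across the package."""


class GazebenchError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GazebenchError):
    """Malformed geometry, scene or evaluation configuration."""


class SchemaError(GazebenchError):
    """A CSV input does not match the documented schema."""


class InputError(GazebenchError):
    """Well-formed file, invalid content (bad rows, unsorted timestamps...)."""


class UnscorableError(GazebenchError):
    """A clip has no scorable frames; raised only where no explicit
    unscorable-result type is available."""
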