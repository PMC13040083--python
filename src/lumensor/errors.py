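"""Exception types shared across the package."""


class LumensorError(Exception):
    """Base class for package errors."""


class ValidationError(LumensorError, ValueError):
    """A parameter or input violates a documented precondition."""


class ConfigError(LumensorError, ValueError):
    """A run configuration is malformed (unknown keys, wrong types, ...)."""


class DataError(LumensorError, ValueError):
    """An input file or table is malformed."""
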