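"""Exception hierarchy shared across the package."""


class PinforgeError(Exception):
    """Base class for all package errors."""


class FormatError(PinforgeError):
    """A file failed to parse or violated a structural invariant."""


class ConfigError(PinforgeError):
    """An invalid configuration value."""


class UsageError(PinforgeError):
    """An operation was called with arguments that make no sense."""
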