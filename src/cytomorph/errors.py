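"""Exception hierarchy shared across the package."""


class CytomorphError(Exception):
    """Base class for all package errors."""


class ConfigError(CytomorphError):
    """Invalid, missing or unknown configuration values."""


class InputError(CytomorphError):
    """Invalid data passed to an operation (dimension mismatch, negative values...)."""


class PlacementError(CytomorphError):
    """A synthetic object cannot be placed inside the field of view."""
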