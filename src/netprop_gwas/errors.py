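"""Exception hierarchy shared across the package."""


class NetpropError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NetpropError):
    """A parameter, column mapping, or run configuration is unusable."""


class InputError(NetpropError):
    """An input file or in-memory input violates a documented precondition."""


class FormatError(InputError):
    """A file does not conform to its declared format (CX, SIF, edge list)."""
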