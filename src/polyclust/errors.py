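"""Exception hierarchy shared across pipeline stages."""


class PolyclustError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PolyclustError):
    """Invalid configuration: missing columns, bad parameter values, unknown keys."""


class ParseError(PolyclustError):
    """Malformed input data (non-numeric fields, bad file structure)."""


class DataError(PolyclustError):
    """Structurally valid input that cannot be analysed (empty intersections, too few rows)."""


class ComputationError(PolyclustError):
    """A numerical operation is undefined for the given input (se=0, p=0, singular design)."""
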