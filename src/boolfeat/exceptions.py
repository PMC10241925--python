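"""Exception hierarchy shared across the package."""


class BoolfeatError(Exception):
    """Base class for package errors."""


class ConfigError(BoolfeatError, ValueError):
    """Invalid configuration (missing label column, bad rates, missing weight)."""


class ParseError(BoolfeatError, ValueError):
    """A data file could not be parsed into a numeric feature table."""


class SchemaError(BoolfeatError, ValueError):
    """Feature names of a scoring table do not match the model's training schema."""


class DegenerateDataError(BoolfeatError, ValueError):
    """Data cannot support the requested operation (single class, constant column, ...)."""


class StructureError(BoolfeatError, ValueError):
    """An expression tree violates arity, typing, or index-range invariants."""
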