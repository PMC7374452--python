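"""Exception hierarchy shared across the package."""


class QsrecError(Exception):
    """Base class for all package errors."""


class DomainError(QsrecError):
    """An argument is outside the domain an operation is defined on."""


class SchemaError(QsrecError):
    """A document or record violates its declared structure."""


class ConfigurationError(QsrecError):
    """A rule, table or config file is malformed or inconsistent."""


class OrderingError(QsrecError):
    """A record would break the time ordering of a history."""


class MappingError(QsrecError):
    """A label is missing from a required lookup table."""


class EvaluationError(QsrecError):
    """A clause or effect could not be evaluated against a state."""
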