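"""Exception hierarchy for ecofoot."""


class EcofootError(Exception):
    """Base class for all ecofoot errors."""


class ConfigurationError(EcofootError):
    """A factor table or run configuration is incomplete or inconsistent."""


class InvalidFactorError(ConfigurationError):
    """A conversion factor (yield, energy footprint, equivalence) is unusable."""


class InvalidRecordError(EcofootError):
    """An account record violates its invariants (e.g. negative production)."""


class SchemaError(EcofootError):
    """An input file does not match the expected schema.

    Messages name the offending file, row and column wherever possible.
    """


class DomainError(EcofootError):
    """A numeric precondition is violated (zero population, n < 4, ...)."""


class FitError(EcofootError):
    """The grey-model least-squares problem is singular or otherwise unsolvable."""
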