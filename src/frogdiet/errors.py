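"""Exception hierarchy shared across the package."""


class FrogdietError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(FrogdietError):
    """Input table violates the documented CSV schema."""


class VocabularyError(SchemaError):
    """A categorical field holds a token outside its closed vocabulary."""


class OrphanRowError(SchemaError):
    """A prey row cannot be attached to a predator individual."""


class DomainError(FrogdietError):
    """A numeric argument is outside its mathematical domain."""


class ImputationError(FrogdietError):
    """Volume imputation has no donor values for a taxon."""


class TraitLookupError(FrogdietError):
    """A taxon is missing from the functional-trait table."""


class UndefinedCompositionError(FrogdietError):
    """Composition metrics requested for a diet with no prey items."""


class UndefinedOverlapError(FrogdietError):
    """Overlap requested for a zero-sum utilization vector."""


class UndefinedElectivityError(FrogdietError):
    """Electivity requested where a consumed group has zero availability."""


class ConfigError(FrogdietError):
    """An analysis or simulation configuration is invalid."""
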