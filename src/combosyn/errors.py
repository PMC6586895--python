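"""Exception hierarchy for the combosyn pipeline."""


class CombosynError(Exception):
    """Base class for all package errors."""


class SchemaError(CombosynError):
    """A required column or field is missing from an input table."""


class ParseError(CombosynError):
    """A row-level value could not be parsed."""


class DuplicateKeyError(CombosynError):
    """A (combination, cell line) key appears more than once."""


class ResolutionError(CombosynError):
    """An identifier could not be resolved against a provider."""


class AssemblyError(CombosynError):
    """Feature-matrix assembly failed (e.g. duplicate feature name)."""


class ConfigError(CombosynError):
    """An invalid configuration value."""


class ChemistryError(CombosynError):
    """A SMILES string could not be parsed by the fingerprint provider."""


class DimensionError(CombosynError):
    """Vector length mismatch."""


class InsufficientSampleError(CombosynError):
    """Too few observations for the requested statistic."""


class MetricUndefinedError(CombosynError):
    """The metric is undefined for the given inputs (e.g. zero total weight)."""


class LabelingError(CombosynError):
    """A combination cannot be labelled (e.g. no scores)."""


class StratificationError(CombosynError):
    """A stratum required by a two-sample test is empty."""


class UnsupportedModelError(CombosynError):
    """The operation requires a different model family."""
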