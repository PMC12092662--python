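"""Exception hierarchy.

Every error raised by the package derives from :class:`MetaCHError` so callers
can catch one type at the CLI boundary.
"""


class MetaCHError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MetaCHError):
    """Invalid configuration: missing column, bad mixture weights, etc."""


class EmptyInputError(MetaCHError):
    """An input table or record list was empty where content is required."""


class LookupError_(MetaCHError):
    """A chromosome or key could not be resolved."""


class CoordinateError(MetaCHError):
    """A variant position falls outside its contig."""


class SchemaError(MetaCHError):
    """A table or model manifest does not match the expected schema."""


class ParseError(MetaCHError):
    """A cell could not be parsed; carries row/column coordinates."""


class TrainingError(MetaCHError):
    """Training preconditions violated (no usable pairs, single class...)."""


class NumericalError(MetaCHError):
    """Non-finite values encountered during optimisation."""


class AggregationError(MetaCHError):
    """Aggregation over an empty collection."""


class ImputationError(MetaCHError):
    """A channel has no observed training values to impute from."""


class LabelError(MetaCHError):
    """Labels missing a required class, or single-class input."""


class FoldError(MetaCHError):
    """Too few examples for the requested number of CV folds."""


class LeakageError(MetaCHError):
    """Stacking inputs were produced by a model that saw the example."""


class EvaluationError(MetaCHError):
    """A metric is undefined for the given labels (e.g. single class)."""


class GroupingError(MetaCHError):
    """A feature group is empty or does not partition the columns."""


class SplitError(MetaCHError):
    """A patient-level split cannot be formed (fewer than 2 patients)."""


class StateError(MetaCHError):
    """An operation requires a fitted model."""
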