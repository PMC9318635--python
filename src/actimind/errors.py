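"""Exception hierarchy shared across the pipeline stages."""


class ActimindError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ActimindError):
    """A subject CSV file violates the expected dialect."""


class ManifestError(ActimindError):
    """A cohort manifest is empty, inconsistent, or self-contradictory."""


class DegenerateDataError(ActimindError):
    """Input data lack the variation a computation requires."""


class SplitError(ActimindError):
    """A train/test partition cannot be formed as requested."""


class StratificationError(ActimindError):
    """Class structure is insufficient for stratified resampling."""


class DataError(ActimindError):
    """Feature data are unusable (missing values, single class, ...)."""


class SchemaError(ActimindError):
    """Feature columns do not match what a fitted model expects."""


class FoldError(ActimindError):
    """Requested cross-validation folds exceed what a class can fill."""


class EmptyDatasetError(ActimindError):
    """An operation received no segments/rows to work on."""
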