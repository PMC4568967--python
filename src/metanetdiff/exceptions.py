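"""Exception hierarchy for metanetdiff."""


class MetanetdiffError(Exception):
    """Base class for all package errors."""


class ConfigError(MetanetdiffError):
    """Invalid configuration (bad fractions, empty level sets, ...)."""


class DataError(MetanetdiffError):
    """Malformed data (negative intensities, p-values outside [0, 1], ...)."""


class AlignmentError(MetanetdiffError):
    """Objects that must share a feature/sample set do not."""


class InsufficientDataError(MetanetdiffError):
    """Too few samples/features for the requested computation."""


class DegeneratePredictorError(MetanetdiffError):
    """A model predictor is constant or otherwise singular."""


class ConfoundingError(MetanetdiffError):
    """Batch perfectly confounded with a covariate of interest."""


class UnimputableError(MetanetdiffError):
    """A sample or feature has no observed values to impute from."""
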