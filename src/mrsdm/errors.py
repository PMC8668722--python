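"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`MultiRealmError`, so callers can catch one type at pipeline
boundaries while still distinguishing failure modes.
"""


class MultiRealmError(Exception):
    """Base class for all mrsdm errors."""


class AlignmentError(MultiRealmError):
    """Gridded inputs do not share extent, resolution or cell index."""


class ConfigurationError(MultiRealmError):
    """Invalid configuration value, unknown realm tag, or missing layer."""


class RealmDomainError(MultiRealmError):
    """An operation's domain precondition failed (e.g. an empty realm)."""


class SamplingError(MultiRealmError):
    """Pseudo-absence sampling could not satisfy its contract."""


class DataError(MultiRealmError):
    """Model input rows violate a data precondition (NaN, too few rows)."""


class FitError(MultiRealmError):
    """A learner could not be fitted (e.g. single-class labels)."""


class SchemaError(MultiRealmError):
    """Rows passed to predict lack a variable the model requires."""


class MetricError(MultiRealmError):
    """A validation metric is undefined for the given inputs."""


class SplitError(MetricError):
    """A train/validation split cannot be stratified."""


class EnsembleError(MultiRealmError):
    """Ensemble construction failed (no gated member, constant map...)."""
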