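"""Exception hierarchy for the squatstab pipeline."""


class SquatStabError(Exception):
    """Base class for all squatstab errors."""


class ConfigurationError(SquatStabError):
    """A configuration value violates an invariant."""


class IngestError(SquatStabError):
    """A raw stream file failed validation on read."""


class SynchronizationError(SquatStabError):
    """Two modality streams cannot be placed on a common grid."""


class ParameterError(SquatStabError):
    """An operation parameter is outside its valid range."""


class UndefinedCorrelationError(SquatStabError):
    """A correlation coefficient is undefined (zero variance / empty margin)."""


class FeatureSetMismatchError(SquatStabError):
    """A model was applied to data with a different feature set."""
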