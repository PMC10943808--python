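"""Exception hierarchy shared across the pipeline."""


class BcellDynError(Exception):
    """Base class for all package errors."""


class FormatError(BcellDynError):
    """A file does not conform to the expected format (e.g. missing column)."""


class ValidationError(BcellDynError):
    """A record or table violates an invariant of the data model."""


class ConsistencyError(BcellDynError):
    """Two inputs contradict each other (e.g. repertoire for a not-collected visit)."""


class ParameterError(BcellDynError):
    """An argument is outside its documented domain."""


class InsufficientDataError(BcellDynError):
    """Not enough observations to compute the requested quantity."""


class UndefinedMetricError(BcellDynError):
    """A metric is undefined on the given input (e.g. empty sample)."""


class InfeasibleTargetError(BcellDynError):
    """A simulation target cannot be realized with the given configuration."""
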