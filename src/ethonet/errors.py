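"""Exception hierarchy shared by all ethonet modules."""


class EthonetError(Exception):
    """Base class for all errors raised by ethonet."""


class FormatError(EthonetError):
    """A file does not conform to the documented tabular layout."""


class ValidationError(EthonetError):
    """Input data violate a structural invariant (ordering, grid, labels)."""


class ParameterError(EthonetError, ValueError):
    """A caller-supplied parameter is outside its documented domain."""


class ConfigurationError(EthonetError):
    """A configuration is internally inconsistent or infeasible."""


class AlignmentError(EthonetError):
    """Two sequences that must be aligned item-by-item differ in length."""


class UndefinedStatisticError(EthonetError):
    """A statistic is mathematically undefined for the given input
    (e.g. Cohen's kappa when expected agreement is 1)."""


class DegenerateInputError(EthonetError):
    """Input is structurally valid but carries no usable signal
    (all-zero matrix, empty repertoires, empty presence matrix)."""


class StratificationError(EthonetError):
    """Objects from different strata (mound types) were mixed, or a
    requested stratum is empty."""


class LookupError_(EthonetError, KeyError):
    """An entity (subject, element, technique, group) is unknown."""


class PipelineStageError(EthonetError):
    """A pipeline stage failed; carries the stage name and an error code."""

    def __init__(self, stage: str, code: str, message: str):
        self.stage = stage
        self.code = code
        super().__init__(f"[{stage}:{code}] {message}")
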