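"""Exception hierarchy shared across the pipeline stages."""


class RespigateError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigurationError(RespigateError):
    """A generator / model / experiment configuration violates its invariants."""


class DegenerateSignalError(RespigateError):
    """A signal has zero spread where nonzero spread is required."""


class InvalidParameterError(RespigateError):
    """An operation parameter is out of its admissible range."""


class EmptyDatasetError(RespigateError):
    """Windowing produced no (input, target) pairs."""


class InvalidSplitError(RespigateError):
    """A train/validation/test split request is impossible."""


class InsufficientCyclesError(RespigateError):
    """Too few peaks/valleys to compute cycle statistics."""


class InvalidCohortError(RespigateError):
    """A cohort is too small for the requested grouping."""


class ShapeError(RespigateError):
    """Tensor dimensions are inconsistent."""


class InvalidInputError(RespigateError):
    """Metric inputs are empty or mismatched."""


class DegenerateInputError(RespigateError):
    """Metric inputs have zero variance."""


class InvalidTrainingError(RespigateError):
    """Training was requested on an empty dataset."""


class DivergenceError(RespigateError):
    """Training loss became non-finite."""


class FormatError(RespigateError):
    """An external file does not conform to the expected format."""
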