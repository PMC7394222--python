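"""Exception hierarchy for the pipeline.

Every stage raises one of these rather than bare ValueError so that the
orchestrator can tag failures with the stage that produced them.
"""


class DFComplexityError(ValueError):
    """Base class for all pipeline errors."""


class InvalidParameterError(DFComplexityError):
    """A parameter is outside its admissible range."""


class InvalidBandError(InvalidParameterError):
    """A frequency band is incompatible with the sampling rate or yields
    degenerate embedding parameters."""


class InsufficientDataError(DFComplexityError):
    """The input series / tensor is too short for the requested analysis."""


class DegenerateSignalError(DFComplexityError):
    """The signal is locally constant where the method requires dispersion."""


class MalformedSpectrumError(DFComplexityError):
    """The singularity spectrum has no usable interior maximum."""


class InvalidDesignError(DFComplexityError):
    """A statistical or cross-validation design constraint is violated."""
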