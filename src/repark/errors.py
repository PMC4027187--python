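"""Exception hierarchy shared across the pipeline stages."""


class ReparkError(Exception):
    """Base class for all repark errors."""


class ParseError(ReparkError):
    """A sequence file is malformed; the message names the offending record."""


class AlphabetError(ReparkError):
    """A sequence contains characters outside the accepted alphabet."""


class ParameterError(ReparkError):
    """A parameter violates a stage's preconditions."""


class ThresholdEstimationError(ReparkError):
    """The k-mer histogram does not support automatic threshold estimation.

    Callers may fall back to supplying an explicit threshold.
    """


class SimulationError(ReparkError):
    """A synthetic-genome or read-simulation request is infeasible."""
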