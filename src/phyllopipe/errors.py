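"""Exception hierarchy shared across the pipeline stages."""


class PhyllopipeError(Exception):
    """Base class for all errors raised by this package."""


class ParameterError(PhyllopipeError, ValueError):
    """An invalid parameter value; the message names the offending field."""


class SequenceFormatError(PhyllopipeError, ValueError):
    """A sequence contains characters outside the accepted nucleotide alphabet."""


class EmptyInputError(PhyllopipeError, ValueError):
    """An operation that requires a nonempty input received an empty one."""


class UnknownIdError(PhyllopipeError, KeyError):
    """A record refers to an identifier absent from the relevant set."""


class DegenerateLibraryError(PhyllopipeError, ValueError):
    """A sequencing library has a zero mapped-read total."""


class NormalizationError(PhyllopipeError, ValueError):
    """Size-factor or reference-gene normalization cannot proceed."""


class DesignError(PhyllopipeError, ValueError):
    """The experimental design does not meet the test's requirements."""


class DegenerateTableError(PhyllopipeError, ValueError):
    """A contingency table has a zero margin."""


class FrameError(PhyllopipeError, ValueError):
    """A coding sequence length is not a multiple of three."""


class FitError(PhyllopipeError, ValueError):
    """A regression fit is impossible (too few or collinear-degenerate points)."""


class InvalidCurveError(PhyllopipeError, ValueError):
    """A standard curve is unusable for quantification (non-negative slope)."""


class InsufficientDataError(PhyllopipeError, ValueError):
    """Fewer data points than the operation minimally requires."""


class ConfigError(PhyllopipeError, ValueError):
    """A pipeline configuration file is invalid (unknown key, bad value)."""
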