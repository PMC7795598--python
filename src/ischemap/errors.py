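"""Exception and warning types shared across the package."""


class IschemapError(Exception):
    """Base class for all ischemap errors."""


class FormatError(IschemapError):
    """A container file is malformed (e.g. a required header field is missing)."""


class MontageError(IschemapError):
    """Lead table and signal matrix disagree, or the montage itself is invalid."""


class NoBeatError(IschemapError):
    """No suprathreshold activity found in a reference trace."""


class EmptyTableError(IschemapError):
    """Every lead of a recording was excluded by quality rules."""


class ParameterError(IschemapError, ValueError):
    """Invalid parameter value passed to a generator or detector."""


class SeparationError(IschemapError):
    """Complete separation: the logistic likelihood has no finite maximiser."""


class ConvergenceError(IschemapError):
    """Iterative fit failed to converge within the iteration budget."""


class WeightNormalizationWarning(UserWarning):
    """Remote-pool weights did not sum to one and were renormalised."""
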