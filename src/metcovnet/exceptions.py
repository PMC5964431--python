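"""Exception hierarchy for metcovnet."""


class MetcovnetError(Exception):
    """Base class for all metcovnet errors."""


class ParameterError(MetcovnetError, ValueError):
    """An argument is outside its documented range or inconsistent."""


class DataError(MetcovnetError, ValueError):
    """Input data violate a contract (empty region, zero variance, ...)."""


class NumericalError(MetcovnetError, RuntimeError):
    """A numerical procedure failed (singular matrix, degenerate nulls)."""


class InferenceError(MetcovnetError, RuntimeError):
    """A statistical procedure produced unusable results."""
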