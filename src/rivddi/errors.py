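"""Exception hierarchy for rivddi."""


class RivddiError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(RivddiError, ValueError):
    """A PK parameter violates its positivity/range invariant."""


class InvalidCovariateError(RivddiError, ValueError):
    """A covariate effect would drive a parameter non-positive."""


class InvalidInputError(RivddiError, ValueError):
    """A function argument is outside its documented domain."""


class InvalidWindowError(RivddiError, ValueError):
    """An integration/regression window lies outside the sampled grid."""


class UndefinedLambdaZError(RivddiError, ValueError):
    """Terminal-slope regression attempted on non-positive concentrations."""


class NumericalError(RivddiError, RuntimeError):
    """ODE solver failure or internal-consistency violation."""


class ConvergenceError(RivddiError, RuntimeError):
    """Iterative procedure did not reach its tolerance."""
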