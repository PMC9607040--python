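"""Exception and warning types used across the solver."""


class PeristreamError(Exception):
    """Base class for all solver errors."""


class DegenerateModeError(PeristreamError):
    """The viscous and acoustic mode wavenumbers coalesce; the closed form is invalid."""


class SingularSystemError(PeristreamError):
    """The 2x2 wall-condition system for the mode amplitudes is numerically singular."""


class ConvergenceError(PeristreamError):
    """The collocation boundary-value solver failed to converge.

    Carries the parameter point in ``args`` for diagnosis.
    """


class ConsistencyError(PeristreamError):
    """An identity that the solution must satisfy (e.g. the mean transverse
    wall balance fixing D1 = 0) is violated beyond tolerance."""


class QuadratureWarning(UserWarning):
    """Adaptive quadrature did not reach the requested tolerance."""
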