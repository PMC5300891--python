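"""Exception hierarchy for loopbind."""


class LoopbindError(Exception):
    """Base class for all loopbind errors."""


class ParameterError(LoopbindError, ValueError):
    """A kinetic parameter or mixture condition is out of its physical domain."""


class InvalidStateError(LoopbindError, ValueError):
    """A species state contains negative or non-finite concentrations."""


class StabilityError(LoopbindError):
    """The requested integrator step size violates the RK4 stability bound."""


class IntegrationError(LoopbindError):
    """Numerical integration produced an unphysical trajectory."""


class ConvergenceError(LoopbindError):
    """An iterative computation did not reach its tolerance.

    Carries the last iterate (if any) in :attr:`last_state` so callers can
    inspect how far the computation got.
    """

    def __init__(self, message, last_state=None):
        super().__init__(message)
        self.last_state = last_state


class FitError(LoopbindError):
    """A least-squares fit failed or returned an unphysical parameter."""


class ConfigError(LoopbindError, ValueError):
    """A configuration file is malformed or fails validation."""
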