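"""Exception hierarchy for hifmir."""


class HifmirError(Exception):
    """Base class for all package errors."""


class ModelDefinitionError(HifmirError):
    """A model references undeclared species/parameters or violates an invariant."""


class StateError(HifmirError):
    """A state vector is inconsistent with the model (e.g. negative concentration)."""


class ConfigurationError(HifmirError):
    """A protocol, perturbation or calibration configuration is invalid."""


class DomainError(HifmirError, ValueError):
    """An input falls outside the physically meaningful domain."""


class ConvergenceError(HifmirError):
    """Steady-state pre-equilibration failed to converge; carries the residual."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class SolverError(HifmirError):
    """The stiff ODE integrator failed; carries the solver diagnostic."""


class NormalizationError(HifmirError):
    """A relative-expression trace could not be normalized (zero at t=0)."""


class CalibrationError(HifmirError):
    """All calibration starts failed."""
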