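"""Exception hierarchy for moodkit."""


class MoodkitError(Exception):
    """Base class for all moodkit errors."""


class InvalidParameterError(MoodkitError, ValueError):
    """A kinetic constant, volume or configuration value is out of its domain."""


class BoundsError(MoodkitError, ValueError):
    """A decision vector violates its box bounds."""


class NumericalStateError(MoodkitError, ValueError):
    """A state vector contains NaN/Inf or is otherwise unusable."""


class EquilibrationError(MoodkitError, RuntimeError):
    """Pre-equilibration failed to reach a fixed point within tolerance."""


class SimulationError(MoodkitError, RuntimeError):
    """The ODE solver failed; carries the decision vector for diagnostics."""

    def __init__(self, message: str, theta=None):
        super().__init__(message)
        self.theta = theta


class EvaluationError(MoodkitError, ValueError):
    """Objective evaluation impossible (e.g. no stimulus applied)."""


class ConfigError(MoodkitError, ValueError):
    """Malformed or inconsistent run configuration."""
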