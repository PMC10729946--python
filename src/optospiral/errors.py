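"""Exception hierarchy shared across the package."""


class OptospiralError(Exception):
    """Base class for all package-specific errors."""


class InvalidStateError(OptospiralError):
    """A cell or tissue state violates a model invariant (NaN, occupancy out of range, ...)."""


class IntegrationError(OptospiralError):
    """The time integrator diverged; carries the last stable time and variable name when known."""

    def __init__(self, message, t_last=None, variable=None):
        super().__init__(message)
        self.t_last = t_last
        self.variable = variable


class StabilityError(OptospiralError):
    """Requested time step violates the documented stability bound."""


class PropagationFailureError(OptospiralError):
    """A stimulated wave failed to reach the measurement probes."""


class SpiralInitError(OptospiralError):
    """Cross-field initiation did not produce a single stable spiral."""


class NoCoreError(OptospiralError):
    """No circular core could be fitted to the frame (also signals completed dissolution)."""


class InsufficientDataError(OptospiralError):
    """Too few valid samples to fit (e.g. fewer than 3 core radii)."""


class NoPeakError(OptospiralError):
    """Spectrum has no peak above the DC-exclusion floor."""


class ConfigError(OptospiralError):
    """Configuration failed validation; message lists the offending keys."""


class RecordingIOError(OptospiralError):
    """Recording file is corrupt or has an unsupported schema version."""
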