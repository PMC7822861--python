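"""Exception hierarchy shared across the package."""


class ActinexError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ActinexError, ValueError):
    """Invalid user input: negative concentration, bad calibration, etc."""


class IntegrationError(ActinexError, RuntimeError):
    """The ODE integrator failed; the message names the condition."""


class CalibrationError(ActinexError, ValueError):
    """Degenerate or unusable anisotropy calibration."""


class FitError(ActinexError, RuntimeError):
    """Optimizer failed to converge; carries diagnostics in the message."""


class EquilibriumError(ActinexError, RuntimeError):
    """No physical root found for the competitive equilibrium (should not
    happen for valid inputs)."""
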