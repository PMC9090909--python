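"""Exception hierarchy.

All user-input problems derive from :class:`ValidationError` so the CLI can
map them to exit code 2; numerical/model problems derive from
:class:`ModelError`.
"""


class PhotokinError(Exception):
    """Base class for all package errors."""


class ValidationError(PhotokinError, ValueError):
    """Invalid user input (bad file, bad value, bad configuration)."""


class ParseError(ValidationError):
    """A CSV/JSON/YAML input violates the expected format."""


class RangeError(ValidationError):
    """A requested grid or value lies outside the covered range."""


class ModelError(PhotokinError):
    """Base class for model-domain problems."""


class DegenerateSystemError(ModelError):
    """Sum of (eps_A - eps_B) over the window is zero: the eta-order
    coefficients are undefined and the first-order limit applies."""


class SimulationError(ModelError):
    """The ODE integrator failed; carries the last good state."""

    def __init__(self, message, t_last=None, c_last=None):
        super().__init__(message)
        self.t_last = t_last
        self.c_last = c_last


class FitError(ModelError):
    """A regression or optimisation did not converge."""


class ProtocolError(ValidationError):
    """The actinometry protocol's preconditions are not met."""


class LampMismatchError(ProtocolError):
    """A calibration was used with a lamp other than the one it was
    measured on (actinometers are lamp-specific)."""
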