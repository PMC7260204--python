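"""Exception types raised by beadscape."""


class BeadscapeError(ValueError):
    """Base class for all beadscape errors."""


class FormatError(BeadscapeError):
    """Malformed or unsupported file content (e.g. OVF dialects)."""


class GeometryError(BeadscapeError):
    """A shape does not fit the requested grid."""


class SingularityError(BeadscapeError):
    """Field or potential requested at a singular point (|r| = 0)."""


class FitRankError(BeadscapeError):
    """Least-squares fit is underdetermined or rank deficient."""


class ConfigurationError(BeadscapeError):
    """Inconsistent run configuration (state counts, modes, ...)."""


class DomainError(BeadscapeError):
    """Evaluation requested outside the fitted extent on a non-periodic axis."""


class IntegrationError(BeadscapeError):
    """The ODE solver failed; carries the last valid state."""

    def __init__(self, message, t=None, state=None):
        super().__init__(message)
        self.t = t
        self.state = state
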