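"""Point-dipole model of the superparamagnetic bead and the drive field.

The bead magnetises along the instantaneous external field with an effective
(fitted) susceptibility chi and no remanence; its stray field is that of a
point dipole at the bead centre.  The dipole moment carries the bead volume:

    m = chi * H_ext * (4 pi / 3) r_mb^3

so chi is the dimensionless scaling constant relating moment density to the
applied field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import SingularityError

__all__ = ["BeadSpec", "FieldSequence", "bead_moment", "dipole_field", "MU0"]

#: vacuum permeability, classical value (T m / A) as used in micromagnetics
MU0 = 4e-7 * math.pi


@dataclass(frozen=True)
class BeadSpec:
    """Superparamagnetic microbead parameters.

    r_mb : bead radius, m.
    chi : effective susceptibility (dimensionless, field-fitted constant).
    rho_mb : bead density, kg/m^3 (polystyrene default).
    Fc : dry-friction coefficient against the substrate (dimensionless).
    """

    r_mb: float
    chi: float
    rho_mb: float = 1050.0
    Fc: float = 0.0

    def __post_init__(self):
        if self.r_mb <= 0:
            raise ValueError("r_mb must be > 0")
        if self.chi < 0:
            raise ValueError("chi must be >= 0")
        if self.rho_mb <= 0:
            raise ValueError("rho_mb must be > 0")
        if self.Fc < 0:
            raise ValueError("Fc must be >= 0")

    @property
    def volume(self):
        return 4.0 / 3.0 * math.pi * self.r_mb**3


@dataclass
class FieldSequence:
    """External drive field mu0*H_ext(t) in tesla.

    mode "rotating": in-plane field of constant amplitude rotating at
    ``frequency`` Hz; ``sense`` +1 is counter-clockwise, -1 clockwise; the
    0 deg position is along +x.  ``n_samples`` field angles per period are
    used when sampling potential maps.

    mode "switching": the field cycles through ``states`` (list of mu0*H
    3-vectors, tesla), each held for an equal fraction of the period;
    ``copies`` is the per-state repetition count used when concatenating
    potential slabs into a square-wave time series for the Fourier fit.
    """

    mode: str
    frequency: float
    amplitude: float = None
    sense: int = 1
    angle0: float = 0.0
    n_samples: int = None
    states: list = None
    copies: int = 100

    def __post_init__(self):
        if self.mode not in ("rotating", "switching"):
            raise ValueError(f"unknown field mode {self.mode!r}")
        if self.frequency <= 0:
            raise ValueError("frequency must be > 0")
        if self.mode == "rotating":
            if self.amplitude is None or self.n_samples is None:
                raise ValueError("rotating mode needs amplitude and n_samples")
        else:
            if not self.states:
                raise ValueError("switching mode needs at least one state")
            self.states = [np.asarray(s, dtype=float) for s in self.states]

    @property
    def period(self):
        return 1.0 / self.frequency

    @property
    def omega(self):
        return 2.0 * math.pi * self.frequency

    @property
    def n_states(self):
        return self.n_samples if self.mode == "rotating" else len(self.states)

    def sample_angles(self):
        """Field angles (deg) of the rotating-mode samples."""
        if self.mode != "rotating":
            raise ValueError("sample_angles is defined for rotating mode only")
        return self.angle0 + self.sense * 360.0 * np.arange(self.n_samples) / self.n_samples

    def state_fields(self):
        """mu0*H (tesla) 3-vectors, one per distinct field state."""
        if self.mode == "rotating":
            ang = np.radians(self.sample_angles())
            return self.amplitude * np.column_stack(
                [np.cos(ang), np.sin(ang), np.zeros_like(ang)]
            )
        return np.asarray(self.states, dtype=float)

    def sample_times(self):
        """Times (s) at which the distinct states are sampled within one period."""
        n = self.n_states
        return self.period * np.arange(n) / n

    def angle_at(self, t):
        """Instantaneous field angle (deg) for rotating mode."""
        if self.mode != "rotating":
            raise ValueError("angle_at is defined for rotating mode only")
        return self.angle0 + self.sense * 360.0 * self.frequency * np.asarray(t)

    def B_at(self, t):
        """Instantaneous mu0*H (tesla) 3-vector at time t."""
        if self.mode == "rotating":
            a = np.radians(self.angle_at(t))
            return self.amplitude * np.array([np.cos(a), np.sin(a), 0.0 * a])
        k = int(np.floor((t % self.period) / self.period * self.n_states))
        return self.states[min(k, self.n_states - 1)]


def bead_moment(bead, H_ext):
    """Bead dipole moment m = chi * H_ext * V_mb, A m^2.

    H_ext is in A/m; zero field gives zero moment.
    """
    H = np.asarray(H_ext, dtype=float)
    return bead.chi * bead.volume * H


def dipole_field(m, r):
    """Stray field H (A/m) of a point dipole with moment ``m`` at displacement
    ``r`` (metres) from the dipole:

        H(r) = (1 / 4 pi) * [3 rhat (m . rhat) - m] / |r|^3
    """
    m = np.asarray(m, dtype=float)
    r = np.asarray(r, dtype=float)
    rn = np.linalg.norm(r, axis=-1, keepdims=True)
    if np.any(rn == 0.0):
        raise SingularityError("dipole field requested at |r| = 0")
    u = r / rn
    mdotu = np.sum(m * u, axis=-1, keepdims=True)
    return (3.0 * u * mdotu - m) / (4.0 * math.pi * rn**3)
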