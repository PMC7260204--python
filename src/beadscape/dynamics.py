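"""Bead equation of motion with wall-corrected drag, friction and gravity.

    m_eff s'' = -Gamma_hd * s' * (1 + 9 r /(16(r+z)),
                                  1 + 9 r /(16(r+z)),
                                  1 + 9 r /( 8(r+z)))  + F_m + F_f [+ F_G]

The bracket is the linear near-wall correction of Stokes drag for a sphere
translating near a plane.  Dry friction acts only while the bead sits on the
substrate (z = 0), proportional to the downward magnetic force, opposing the
motion.  Gravity (buoyancy-corrected) enters only during free 3-D motion.

The solver advances in steps of at most ``max_dt`` (default 0.7 ms).  At the
start of each step the regime is chosen from the previous step's
out-of-plane force: at ground level with no net upward force the in-plane
2-D equation is solved with z frozen; otherwise the full 3-D equation
including gravity is used.  A step that ends below the surface is clamped to
z = 0 with the vertical velocity zeroed.  The active fitting submatrix is
re-centred on the nearest grid node after every step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .errors import DomainError, IntegrationError

__all__ = [
    "EnvironmentSpec",
    "Trajectory",
    "viscosity_water",
    "drag_gamma",
    "wall_drag_factors",
    "effective_mass",
    "gravity_force",
    "friction_force",
    "simulate",
]

_V_EPS = 1e-8  # m/s; friction direction regularisation scale


def viscosity_water(T):
    """Dynamic viscosity of water (Pa s) from temperature (deg C).

    Vogel-type correlation eta = A * 10^(B / (T_K - C)) with A = 2.414e-5
    Pa s, B = 247.8 K, C = 140 K; reproduces handbook values within ~1% over
    0-100 deg C.
    """
    if not 0.0 <= T <= 100.0:
        raise DomainError("viscosity correlation is valid for 0..100 deg C")
    return 2.414e-5 * 10.0 ** (247.8 / (T + 273.15 - 140.0))


@dataclass(frozen=True)
class EnvironmentSpec:
    """Aqueous environment around the bead.

    eta is computed from ``temperature`` unless given explicitly.
    """

    temperature: float = 22.0
    eta: float = None
    rho_water: float = 998.0
    g: float = 9.81

    def __post_init__(self):
        if self.eta is None:
            object.__setattr__(self, "eta", viscosity_water(self.temperature))
        if self.eta <= 0:
            raise ValueError("eta must be > 0")


def drag_gamma(bead, env):
    """Linear hydrodynamic damping parameter Gamma_hd = 6 pi eta r_mb (kg/s)."""
    return 6.0 * math.pi * env.eta * bead.r_mb


def wall_drag_factors(r_mb, z):
    """Near-wall drag correction factors (fx, fy, fz) at bead height z.

    In-plane: 1 + 9 r/(16 (r+z)); out-of-plane: 1 + 9 r/(8 (r+z)).
    """
    q = r_mb / (r_mb + z)
    fxy = 1.0 + 9.0 / 16.0 * q
    return (fxy, fxy, 1.0 + 9.0 / 8.0 * q)


def effective_mass(bead, env):
    """Added-mass-corrected inertia (4 pi/3) r^3 (rho_mb + rho_water/2), kg."""
    return bead.volume * (bead.rho_mb + env.rho_water / 2.0)


def gravity_force(bead, env):
    """Buoyancy-corrected weight along -z, newtons (scalar, <= 0 for
    beads denser than water)."""
    return -(bead.rho_mb - env.rho_water) * bead.volume * env.g


def friction_force(bead, F_m, v, z):
    """Dry friction F_f = -Fc * max(0, -F_mz) * v/|v| at the substrate.

    Nonzero only at z = 0 with the bead moving; only the downward magnetic
    force component generates friction (an upward force means imminent
    lift-off).  No static friction: at rest the direction is undefined and
    F_f = 0.
    """
    v = np.asarray(v, dtype=float)
    if z != 0.0:
        return np.zeros(3)
    speed = np.linalg.norm(v)
    if speed == 0.0:
        return np.zeros(3)
    load = max(0.0, -float(np.asarray(F_m)[2]))
    return -bead.Fc * load * v / speed


@dataclass
class Trajectory:
    """Time-sampled bead state.

    Positions are stored both wrapped into the map extent (periodic axes)
    and unwrapped (cumulative).  ``regime`` is 2 or 3 per sample.  ``events``
    is a chronological list of dicts (floor clamps, boundary wraps,
    submatrix hops, regime switches).
    """

    t: np.ndarray
    pos: np.ndarray
    pos_unwrapped: np.ndarray
    vel: np.ndarray
    regime: np.ndarray
    events: list = field(default_factory=list)

    def __post_init__(self):
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.pos[:, 2].min() < 0:
            raise ValueError("trajectory contains z < 0 samples")

    @property
    def speed(self):
        return np.linalg.norm(self.vel, axis=1)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t": self.t,
                "x": self.pos[:, 0],
                "y": self.pos[:, 1],
                "z": self.pos[:, 2],
                "x_unwrapped": self.pos_unwrapped[:, 0],
                "y_unwrapped": self.pos_unwrapped[:, 1],
                "vx": self.vel[:, 0],
                "vy": self.vel[:, 1],
                "vz": self.vel[:, 2],
                "regime": self.regime,
            }
        )


def _wrap(value, lo, L):
    return lo + (value - lo) % L


def _solve_step(rhs, t, t_next, y0, method, rtol, atol, max_dt):
    """One solver step; falls back to an implicit Runge-Kutta method when the
    multistep solver reports convergence trouble (near-discontinuous friction
    at the onset of rest intervals)."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sol = solve_ivp(rhs, (t, t_next), y0, method=method, rtol=rtol,
                        atol=atol, max_step=max_dt)
        if not sol.success:
            sol = solve_ivp(rhs, (t, t_next), y0, method="Radau", rtol=rtol,
                            atol=atol, max_step=max_dt)
    return sol


def simulate(
    fit,
    bead,
    env,
    field_seq=None,
    s0=(0.0, 0.0, 0.0),
    t_span=1.0,
    max_dt=7e-4,
    rtol=1e-8,
    atol_pos=1e-12,
    atol_vel=1e-13,
    v0=(0.0, 0.0, 0.0),
    method="LSODA",
):
    """Integrate the bead equation of motion over ``t_span`` seconds.

    ``fit`` supplies the magnetic force; ``field_seq`` is carried along for
    metadata only (the drive enters through the fitted time dependence).
    Positions are integrated unwrapped; wrapped coordinates and an event log
    are produced alongside.  Returns a :class:`Trajectory` sampled at the
    step boundaries (spacing ``max_dt``).
    """
    del field_seq
    gamma = drag_gamma(bead, env)
    m_eff = effective_mass(bead, env)
    Fg = gravity_force(bead, env)
    r = bead.r_mb
    events = []

    spec = fit.spec
    lx, ly = spec.lengths
    x0r, y0r = spec.x_range[0], spec.y_range[0]
    per_x, per_y = spec.periodic

    pos = np.array(s0, dtype=float)
    vel = np.array(v0, dtype=float)
    t = 0.0
    centre = fit.nearest_node(pos)
    regime = 2

    n_steps = int(math.ceil(t_span / max_dt))
    ts = np.empty(n_steps + 1)
    P = np.empty((n_steps + 1, 3))
    V = np.empty((n_steps + 1, 3))
    R = np.empty(n_steps + 1, dtype=int)
    ts[0], P[0], V[0], R[0] = t, pos, vel, regime

    def force_z(tq, sq, ctr):
        return fit.eval_force(tq, sq, centre=ctr)[2] + Fg

    atol3 = [atol_pos] * 3 + [atol_vel] * 3
    atol2 = [atol_pos] * 2 + [atol_vel] * 2

    for i in range(1, n_steps + 1):
        t_next = min(t + max_dt, t_span)
        # regime from the previous step's out-of-plane force (gravity incl.)
        fz = force_z(t, pos, centre)
        new_regime = 2 if (pos[2] <= 0.0 and fz <= 0.0) else 3
        if new_regime != regime:
            events.append({"t": t, "kind": "regime", "regime": new_regime})
        regime = new_regime

        if regime == 2:

            def rhs2(tq, y):
                s = np.array([y[0], y[1], 0.0])
                v = y[2:]
                Fm = fit.eval_force(tq, s, centre=centre)
                speed = math.hypot(v[0], v[1])
                load = max(0.0, -Fm[2])
                fric = -bead.Fc * load / (speed + _V_EPS)
                fxy = 1.0 + 9.0 / 16.0
                ax = (-gamma * v[0] * fxy + Fm[0] + fric * v[0]) / m_eff
                ay = (-gamma * v[1] * fxy + Fm[1] + fric * v[1]) / m_eff
                return [v[0], v[1], ax, ay]

            y0 = [pos[0], pos[1], vel[0], vel[1]]
            sol = _solve_step(rhs2, t, t_next, y0, method, rtol, atol2, max_dt)
            if not sol.success:
                raise IntegrationError(
                    f"2-D step failed at t={t:.6g}: {sol.message}", t=t,
                    state=(pos.copy(), vel.copy()),
                )
            pos = np.array([sol.y[0, -1], sol.y[1, -1], 0.0])
            vel = np.array([sol.y[2, -1], sol.y[3, -1], 0.0])
        else:

            def rhs3(tq, y):
                s = y[:3]
                v = y[3:]
                Fm = fit.eval_force(tq, s, centre=centre)
                q = r / (r + y[2])
                fxy = 1.0 + 9.0 / 16.0 * q
                fz_fac = 1.0 + 9.0 / 8.0 * q
                ax = (-gamma * v[0] * fxy + Fm[0]) / m_eff
                ay = (-gamma * v[1] * fxy + Fm[1]) / m_eff
                az = (-gamma * v[2] * fz_fac + Fm[2] + Fg) / m_eff
                return [v[0], v[1], v[2], ax, ay, az]

            y0 = np.concatenate([pos, vel])
            sol = _solve_step(rhs3, t, t_next, y0, method, rtol, atol3, max_dt)
            if not sol.success:
                raise IntegrationError(
                    f"3-D step failed at t={t:.6g}: {sol.message}", t=t,
                    state=(pos.copy(), vel.copy()),
                )
            pos = sol.y[:3, -1].copy()
            vel = sol.y[3:, -1].copy()
            if pos[2] < 0.0:
                events.append({"t": t_next, "kind": "floor_clamp", "z": float(pos[2])})
                pos[2] = 0.0
                vel[2] = 0.0

        t = t_next
        new_centre = fit.nearest_node(pos, prev=centre)
        if new_centre != centre:
            events.append({"t": t, "kind": "hop", "from": centre, "to": new_centre})
            centre = new_centre
        ts[i], P[i], V[i], R[i] = t, pos, vel, regime

    Pw = P.copy()
    if per_x:
        wrapped_x = _wrap(P[:, 0], x0r, lx)
        cross = np.diff(np.floor((P[:, 0] - x0r) / lx))
        for j in np.nonzero(cross)[0]:
            events.append({"t": float(ts[j + 1]), "kind": "wrap", "axis": "x"})
        Pw[:, 0] = wrapped_x
    if per_y:
        wrapped_y = _wrap(P[:, 1], y0r, ly)
        cross = np.diff(np.floor((P[:, 1] - y0r) / ly))
        for j in np.nonzero(cross)[0]:
            events.append({"t": float(ts[j + 1]), "kind": "wrap", "axis": "y"})
        Pw[:, 1] = wrapped_y
    events.sort(key=lambda e: e["t"])
    return Trajectory(t=ts, pos=Pw, pos_unwrapped=P, vel=V, regime=R, events=events)
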