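"""Preset builders and the end-to-end pipeline for the four study systems.

Scenarios
---------
disc      : 8 um bead circling a 15 um-radius, 30 nm permalloy disc under a
            20 mT field rotating at 0.9 Hz (looping regime).
triangles : 8 um bead stepping in +y across a hexagonal lattice of 15 um,
            50 nm permalloy triangles, 20 mT switching 30/150 deg at 1 Hz.
stripes   : 2.8 um bead dragged across 10 um exchange-biased microstripes by
            a 4-state (Hy, Hz) switching sequence at 3 Hz.
ovals     : 8 um bead transported along a track of asymmetric FeCoSiB ovals
            by a 20 mT field rotating clockwise at 1 Hz.

Each preset reproduces the published parameter set; the ``coarse`` profile
scales grid resolutions down for desk-scale runs while keeping every
physical parameter unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .analysis import TrajectoryMetrics, detect_looping, detect_rests, phase_lag, radial_position
from .dipole import MU0, BeadSpec, FieldSequence
from .dynamics import EnvironmentSpec, simulate
from .fitting import fit_potential
from .geometry import Disc, Oval, StripeArray, TriangleLattice
from .grids import synth_state
from .potential import PotentialGridSpec, potential_sequence

__all__ = ["ScenarioConfig", "ScenarioResult", "SCENARIO_CONSTANTS", "build_scenario", "run_scenario"]


#: Published parameter values the presets are built from (SI units).
SCENARIO_CONSTANTS = {
    "chi": 0.0256,                   # bead susceptibility (scaling constant)
    "Fc": 0.03,                      # friction coefficient
    "bead_radius": 4e-6,             # 8 um diameter beads
    "stripe_bead_radius": 1.4e-6,    # 2.8 um diameter beads (stripes)
    "water_temperature_C": 22.0,
    "Js_NiFe": 1.0,                  # permalloy saturation polarization, T
    "Js_FeCoSiB": 1.5,               # FeCoSiB saturation polarization, T
    "field_amplitude_T": 20e-3,      # mu0 Hext
    "disc": {
        "radius": 15e-6,
        "film_thickness": 30e-9,
        "frequency": 0.9,
        "fourier_order": 30,
        "n_z_layers_full": 41,
        "z_top_over_r": 3.0,
        "extra_layer_below": -200e-9,
        "grid_nodes_full": 200,
        "max_dt": 7e-4,
    },
    "triangles": {
        "side": 15e-6,
        "film_thickness": 50e-9,
        "frequency": 1.0,
        "switch_angles_deg": (30.0, 150.0),
        "fourier_order": 100,
        "copies_per_state": 100,
        "cell": (2048 * 17.8e-9, 1024 * 20.5e-9),
        "grid_nodes_full": 100,
        "z_top": 12e-6,
        "n_z_layers_full": 22,
    },
    "stripes": {
        "width": 10e-6,
        "period": 12.5e-6,
        "film_thickness": 20e-9,
        "frequency": 3.0,
        "Hy_T": (0.0, 5e-3),
        "Hz_T": (-2.5e-3, 2.5e-3),
        "fourier_order": 50,
        "copies_per_state": 50,
        "z_top": 4.2e-6,
        "n_z_layers_full": 16,
        "n_images_x_full": 300,
    },
    "ovals": {
        "box": (26e-6, 21e-6),
        "film_thickness": 50e-9,
        "frequency": 1.0,
        "n_field_angles": 180,
        "fourier_order": 30,
        "grid_nodes_full": 125,
        "n_z_layers": 6,
    },
}


@dataclass
class ScenarioConfig:
    """Fully specified simulation run (SI units throughout)."""

    name: str
    geometry: object
    film_thickness: float
    Ms: float
    bead: BeadSpec
    env: EnvironmentSpec
    field: FieldSequence
    parent_n_cells: tuple
    parent_cell_size: tuple
    parent_origin: tuple
    parent_periodic: tuple
    parent_images: tuple
    grid: PotentialGridSpec
    follow_field: bool
    magnetization_direction: tuple
    fourier_order: int
    submatrix: int
    copies_per_state: int
    s0: tuple
    t_span: float
    max_dt: float
    analysis: dict = field(default_factory=dict)
    coarse: bool = False

    def replace(self, **kw):
        return replace(self, **kw)


def _unit(angle_deg):
    a = math.radians(angle_deg)
    return (math.cos(a), math.sin(a), 0.0)


def _parent_origin(nx, ny, nz, dx, dy, dz, thickness):
    # structure centred in xy, film top surface at z = 0
    del thickness
    return (-(nx - 1) / 2 * dx, -(ny - 1) / 2 * dy, -nz * dz + dz / 2)


def build_scenario(name, coarse=False, overrides=None):
    """Build the named preset; ``overrides`` is a {field: value} dict applied
    on the finished config (nested objects are replaced wholesale)."""
    C = SCENARIO_CONSTANTS
    chi, Fc = C["chi"], C["Fc"]
    amp = C["field_amplitude_T"]
    env = EnvironmentSpec(temperature=C["water_temperature_C"])

    if name == "disc":
        P = C["disc"]
        R, t = P["radius"], P["film_thickness"]
        Ms = C["Js_NiFe"] / MU0
        bead = BeadSpec(r_mb=C["bead_radius"], chi=chi, Fc=Fc)
        extent = 30.6e-6  # parent frame, slightly over the 30 um diameter
        if coarse:
            pn, gn, nz_layers, n_ang = 96, 64, 9, 90
        else:
            pn, gn, nz_layers, n_ang = 170, P["grid_nodes_full"], P["n_z_layers_full"], 120
        dxy = extent / pn
        z_layers = np.concatenate(
            [[P["extra_layer_below"]], np.linspace(0, P["z_top_over_r"] * bead.r_mb, nz_layers)]
        )
        half = 32e-6
        cfg = ScenarioConfig(
            name=name,
            geometry=Disc(R),
            film_thickness=t,
            Ms=Ms,
            bead=bead,
            env=env,
            field=FieldSequence("rotating", P["frequency"], amplitude=amp, sense=1, n_samples=n_ang),
            parent_n_cells=(pn, pn, 1),
            parent_cell_size=(dxy, dxy, t),
            parent_origin=_parent_origin(pn, pn, 1, dxy, dxy, t, t),
            parent_periodic=(False, False),
            parent_images=(0, 0),
            grid=PotentialGridSpec(
                x_range=(-half, half),
                y_range=(-half, half),
                n_nodes=(gn, gn),
                z_layers=z_layers,
            ),
            follow_field=True,
            magnetization_direction=(1.0, 0.0, 0.0),
            fourier_order=P["fourier_order"],
            submatrix=3,
            copies_per_state=1,
            s0=(R + bead.r_mb, 0.0, 0.0),
            t_span=6.5 / P["frequency"],
            max_dt=P["max_dt"],
            analysis={"centre": (0.0, 0.0), "structure_radius": R},
            coarse=coarse,
        )

    elif name == "triangles":
        P = C["triangles"]
        side, t = P["side"], P["film_thickness"]
        lx, ly = P["cell"]
        Ms = C["Js_NiFe"] / MU0
        bead = BeadSpec(r_mb=C["bead_radius"], chi=chi, Fc=Fc)
        if coarse:
            pnx, pny, gnx, gny, nzl = 126, 72, 64, 40, 8
        else:
            pnx, pny, gnx, gny, nzl = 512, 256, P["grid_nodes_full"], P["grid_nodes_full"], P["n_z_layers_full"]
        z_layers = np.concatenate([[-200e-9], np.linspace(0, P["z_top"], nzl)])
        a1, a2 = P["switch_angles_deg"]
        states = [tuple(amp * u for u in _unit(a1)), tuple(amp * u for u in _unit(a2))]
        cfg = ScenarioConfig(
            name=name,
            # vertex-up orientation: mirror axes along 30/150 deg, +y transport
            geometry=TriangleLattice(side, (lx, ly), vertex_angles=(90.0, 210.0, 330.0)),
            film_thickness=t,
            Ms=Ms,
            bead=bead,
            env=env,
            field=FieldSequence(
                "switching", P["frequency"], states=states, copies=P["copies_per_state"]
            ),
            parent_n_cells=(pnx, pny, 1),
            parent_cell_size=(lx / pnx, ly / pny, t),
            parent_origin=(lx / pnx / 2, ly / pny / 2, -t / 2),
            parent_periodic=(True, True),
            parent_images=(1, 1),
            grid=PotentialGridSpec(
                x_range=(0.0, lx),
                y_range=(0.0, ly),
                n_nodes=(gnx, gny),
                z_layers=z_layers,
                periodic=(True, True),
                n_images=(1, 1),
            ),
            follow_field=True,
            magnetization_direction=_unit(a1),
            fourier_order=P["fourier_order"],
            submatrix=3,
            copies_per_state=P["copies_per_state"],
            s0=(lx / 2, ly / 2 + side / math.sqrt(3.0), 0.0),
            t_span=4.5 / P["frequency"],
            max_dt=7e-4,
            analysis={"transport_axis": 1},
            coarse=coarse,
        )

    elif name == "stripes":
        P = C["stripes"]
        w, per, t = P["width"], P["period"], P["film_thickness"]
        Ms = C["Js_NiFe"] / MU0
        bead = BeadSpec(r_mb=C["stripe_bead_radius"], chi=chi, Fc=Fc)
        if coarse:
            pnx, pny, gnx, gny, nzl, nix = 2, 125, 8, 64, 8, 150
        else:
            pnx, pny, gnx, gny, nzl, nix = 8, 1024, 8, 100, P["n_z_layers_full"], P["n_images_x_full"]
        sect = 100e-9  # narrow x section of the quasi-infinite stripes
        z_layers = np.concatenate([[-200e-9], np.linspace(0, P["z_top"], nzl)])
        hy0, hy1 = P["Hy_T"]
        hz0, hz1 = P["Hz_T"]
        # phase-shifted square waves -> effective 4-step sequence
        states = [(0.0, hy0, hz0), (0.0, hy1, hz0), (0.0, hy1, hz1), (0.0, hy0, hz1)]
        cfg = ScenarioConfig(
            name=name,
            geometry=StripeArray(w, per),
            film_thickness=t,
            Ms=Ms,
            bead=bead,
            env=env,
            field=FieldSequence(
                "switching", P["frequency"], states=states, copies=P["copies_per_state"]
            ),
            parent_n_cells=(pnx, pny, 1),
            parent_cell_size=(sect / pnx, per / pny, t),
            parent_origin=(sect / pnx / 2, per / pny / 2, -t / 2),
            parent_periodic=(True, True),
            parent_images=(nix, 1),
            grid=PotentialGridSpec(
                x_range=(0.0, sect),
                y_range=(0.0, per),
                n_nodes=(gnx, gny),
                z_layers=z_layers,
                periodic=(True, True),
                n_images=(nix, 1),
            ),
            follow_field=False,
            magnetization_direction=(0.0, -1.0, 0.0),  # exchange-bias set
            fourier_order=P["fourier_order"],
            submatrix=3,
            copies_per_state=P["copies_per_state"],
            s0=(sect / 2, w, 0.0),  # upper stripe edge: the first state's minimum
            t_span=2.0 / P["frequency"],
            max_dt=7e-4,
            analysis={"transport_axis": 1, "stripe_period": per, "stripe_width": w},
            coarse=coarse,
        )

    elif name == "ovals":
        P = C["ovals"]
        box = P["box"]
        t = P["film_thickness"]
        Ms = C["Js_FeCoSiB"] / MU0
        bead = BeadSpec(r_mb=C["bead_radius"], chi=chi, Fc=Fc)
        pitch = 30e-6  # track period: 26 um element + 4 um gap
        if coarse:
            pnx, pny, gnx, gny = 150, 105, 64, 48
        else:
            pnx, pny, gnx, gny = 256, 180, P["grid_nodes_full"], P["grid_nodes_full"]
        z_layers = np.linspace(-bead.r_mb / 2, 2 * bead.r_mb, P["n_z_layers"])
        cfg = ScenarioConfig(
            name=name,
            geometry=Oval(length=box[0], height=box[1]),
            film_thickness=t,
            Ms=Ms,
            bead=bead,
            env=env,
            field=FieldSequence(
                "rotating", P["frequency"], amplitude=amp, sense=-1,
                n_samples=P["n_field_angles"],
            ),
            parent_n_cells=(pnx, pny, 1),
            parent_cell_size=(pitch / pnx, box[1] / pny, t),
            parent_origin=_parent_origin(pnx, pny, 1, pitch / pnx, box[1] / pny, t, t),
            parent_periodic=(True, False),
            parent_images=(1, 0),
            grid=PotentialGridSpec(
                x_range=(-pitch / 2, pitch / 2),
                y_range=(-15e-6, 15e-6),
                n_nodes=(gnx, gny),
                z_layers=z_layers,
                periodic=(True, False),
                n_images=(1, 0),
            ),
            follow_field=True,
            magnetization_direction=(1.0, 0.0, 0.0),
            fourier_order=P["fourier_order"],
            submatrix=3,
            copies_per_state=1,
            s0=(pitch / 2, 0.0, 0.0),
            t_span=2.5 / P["frequency"],
            max_dt=7e-4,
            analysis={
                "track_pitch": pitch,
                "rest_speed_floor": 1e-6,
                "rest_min_duration": 0.02,
            },
            coarse=coarse,
        )
    else:
        raise ValueError(f"unknown scenario {name!r}")

    if overrides:
        cfg = cfg.replace(**overrides)
    return cfg


@dataclass
class ScenarioResult:
    config: ScenarioConfig
    grid: object
    pmap: object
    fit: object
    trajectory: object
    metrics: TrajectoryMetrics


def _build_parent(cfg):
    return synth_state(
        cfg.geometry,
        cfg.magnetization_direction,
        cfg.Ms,
        cfg.parent_n_cells,
        cfg.parent_cell_size,
        origin=cfg.parent_origin,
        periodic=cfg.parent_periodic,
        n_images=cfg.parent_images,
    )


def compute_metrics(traj, cfg):
    """Scenario-appropriate trajectory metrics."""
    m = TrajectoryMetrics(z=traj.pos[:, 2].copy())
    a = cfg.analysis
    period = cfg.field.period
    after_first = traj.t >= period
    m.extras["max_z_after_first_period_m"] = float(traj.pos[after_first, 2].max())
    if "centre" in a:
        centre = a["centre"]
        m.phase_lag_deg = phase_lag(traj, cfg.field, centre)
        m.radial = radial_position(traj, centre)
        m.looping_events = detect_looping(
            traj, centre, a["structure_radius"], cfg.bead.r_mb
        )
    if "rest_speed_floor" in a:
        rests = detect_rests(
            traj, speed_floor=a["rest_speed_floor"], min_duration=a["rest_min_duration"]
        )
        # discard an interval that starts at t = 0 (initial placement)
        m.rest_intervals = [r for r in rests if r.t_start > 0.0]
    if "transport_axis" in a:
        ax = a["transport_axis"]
        n_per = int(traj.t[-1] // period)
        if n_per >= 1:
            d = (
                traj.pos_unwrapped[traj.t <= n_per * period][-1]
                - traj.pos_unwrapped[0]
            ) / n_per
            m.net_displacement_per_period = tuple(d)
        m.extras["net_transport_m"] = float(
            traj.pos_unwrapped[-1, ax] - traj.pos_unwrapped[0, ax]
        )
    return m


def run_scenario(cfg, log=None):
    """Full pipeline: synthetic states -> potential map -> fit -> trajectory
    -> metrics.  Returns a :class:`ScenarioResult`."""

    def say(msg):
        if log:
            log(msg)

    say(f"[{cfg.name}] building parent magnetization grid")
    grid = _build_parent(cfg)
    say(f"[{cfg.name}] computing potential map ({cfg.field.n_states} states)")
    pmap = potential_sequence(grid, cfg.bead, cfg.field, cfg.grid, follow_field=cfg.follow_field)
    say(f"[{cfg.name}] fitting (N={cfg.fourier_order}, submatrix {cfg.submatrix})")
    fit = fit_potential(
        pmap,
        cfg.fourier_order,
        submatrix=cfg.submatrix,
        copies_per_state=cfg.copies_per_state if cfg.field.mode == "switching" else None,
    )
    say(f"[{cfg.name}] integrating {cfg.t_span:.3g} s of motion")
    traj = simulate(
        fit,
        cfg.bead,
        cfg.env,
        field_seq=cfg.field,
        s0=cfg.s0,
        t_span=cfg.t_span,
        max_dt=cfg.max_dt,
    )
    say(f"[{cfg.name}] computing metrics")
    metrics = compute_metrics(traj, cfg)
    return ScenarioResult(
        config=cfg, grid=grid, pmap=pmap, fit=fit, trajectory=traj, metrics=metrics
    )
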