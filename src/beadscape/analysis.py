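"""Trajectory metrics: phase lag, radial/z excursions, looping, rest times."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "TrajectoryMetrics",
    "phase_lag",
    "radial_position",
    "detect_looping",
    "detect_rests",
]


@dataclass
class LoopingEvent:
    t_start: float
    t_end: float
    max_radius: float
    max_z: float


@dataclass
class RestInterval:
    t_start: float
    duration: float


@dataclass
class TrajectoryMetrics:
    """Container for per-scenario trajectory metrics."""

    phase_lag_deg: np.ndarray = None
    radial: np.ndarray = None
    z: np.ndarray = None
    looping_events: list = field(default_factory=list)
    rest_intervals: list = field(default_factory=list)
    net_displacement_per_period: tuple = None
    extras: dict = field(default_factory=dict)

    def to_dict(self):
        d = {}
        if self.phase_lag_deg is not None:
            d["phase_lag_final_deg"] = float(self.phase_lag_deg[-1])
        if self.z is not None:
            d["max_z_m"] = float(np.max(self.z))
        d["n_looping_events"] = len(self.looping_events)
        if self.looping_events:
            d["looping_max_z_m"] = max(e.max_z for e in self.looping_events)
            d["looping_max_radius_m"] = max(e.max_radius for e in self.looping_events)
        d["n_rest_intervals"] = len(self.rest_intervals)
        if self.rest_intervals:
            d["median_rest_duration_s"] = float(
                np.median([r.duration for r in self.rest_intervals])
            )
        if self.net_displacement_per_period is not None:
            d["net_displacement_per_period_m"] = [
                float(v) for v in self.net_displacement_per_period
            ]
        d.update(self.extras)
        return d


def radial_position(traj, centre):
    """In-plane distance of the bead from ``centre`` at each sample."""
    dx = traj.pos_unwrapped[:, 0] - centre[0]
    dy = traj.pos_unwrapped[:, 1] - centre[1]
    return np.hypot(dx, dy)


def phase_lag(traj, field_seq, centre):
    """Field angle minus bead azimuth about ``centre``, unwrapped degrees.

    A synchronously circulating bead has a constant lag; each looping event
    adds 360 deg (the bead loses one field turn).
    """
    if field_seq.mode != "rotating":
        raise ConfigurationError("phase lag is defined for rotating fields only")
    az = np.degrees(
        np.unwrap(
            np.arctan2(
                traj.pos_unwrapped[:, 1] - centre[1],
                traj.pos_unwrapped[:, 0] - centre[0],
            )
        )
    )
    lag = field_seq.angle_at(traj.t) - az
    return field_seq.sense * (lag - lag[0])


def detect_looping(traj, centre, structure_radius, r_mb, threshold=None):
    """Maximal radial excursions beyond the circulation radius.

    An event is an interval where the radial distance from ``centre``
    exceeds ``structure_radius + r_mb + threshold`` (default 0.5 r_mb) and
    returns below it; an excursion still open at the end of the trajectory
    is not counted.
    """
    if threshold is None:
        threshold = 0.5 * r_mb
    rad = radial_position(traj, centre)
    z = traj.pos[:, 2]
    above = rad > structure_radius + r_mb + threshold
    events = []
    start = None
    for i in range(len(above)):
        if above[i] and start is None:
            start = i
        elif not above[i] and start is not None:
            events.append(
                LoopingEvent(
                    t_start=float(traj.t[start]),
                    t_end=float(traj.t[i]),
                    max_radius=float(rad[start:i].max()),
                    max_z=float(z[start:i].max()),
                )
            )
            start = None
    return events


def detect_rests(traj, speed_floor=1e-6, min_duration=0.0):
    """Maximal intervals with |v| < speed_floor lasting >= min_duration."""
    below = traj.speed < speed_floor
    rests = []
    start = None
    n = len(below)
    for i in range(n + 1):
        active = below[i] if i < n else False
        if active and start is None:
            start = i
        elif not active and start is not None:
            dur = float(traj.t[i - 1] - traj.t[start])
            if dur >= min_duration and i - 1 > start:
                rests.append(RestInterval(t_start=float(traj.t[start]), duration=dur))
            start = None
    return rests
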