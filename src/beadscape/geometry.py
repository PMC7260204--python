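"""Planar footprints of the patterned soft-magnetic parent structures.

Every shape exposes ``contains(x, y)`` (vectorised point-in-shape test on cell
centres, metres) and ``area()``.  Shapes that tile a periodic unit cell
(:class:`TriangleLattice`, :class:`StripeArray`) are tested modulo their cell
and report ``bounds = None`` so grid-extent checks are skipped for them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely

from .errors import GeometryError

__all__ = ["Disc", "Triangle", "TriangleLattice", "StripeArray", "Oval"]


@dataclass(frozen=True)
class Disc:
    """Circular element of given radius centred at ``centre``."""

    radius: float
    centre: tuple[float, float] = (0.0, 0.0)

    def contains(self, x, y):
        return (x - self.centre[0]) ** 2 + (y - self.centre[1]) ** 2 <= self.radius**2

    def area(self):
        return math.pi * self.radius**2

    def bounds(self):
        cx, cy = self.centre
        r = self.radius
        return (cx - r, cx + r, cy - r, cy + r)


@dataclass(frozen=True)
class Triangle:
    """Equilateral triangle of side ``side`` with vertices at the given polar
    angles (degrees) on the circumcircle around ``centre``.

    The default orientation (vertices at 30, 150, 270 deg) has mirror axes
    along 30, 150 and 270 deg, matching drive fields applied along two of the
    mirror axes.
    """

    side: float
    centre: tuple[float, float] = (0.0, 0.0)
    vertex_angles: tuple[float, float, float] = (30.0, 150.0, 270.0)

    @property
    def vertices(self):
        rc = self.side / math.sqrt(3.0)
        return np.array(
            [
                (
                    self.centre[0] + rc * math.cos(math.radians(a)),
                    self.centre[1] + rc * math.sin(math.radians(a)),
                )
                for a in self.vertex_angles
            ]
        )

    def contains(self, x, y):
        v = self.vertices
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        inside = np.ones(np.broadcast(x, y).shape, dtype=bool)
        # convex polygon: consistent sign of the cross product for each edge
        orient = _polygon_orientation(v)
        for i in range(3):
            ax, ay = v[i]
            bx, by = v[(i + 1) % 3]
            cross = (bx - ax) * (y - ay) - (by - ay) * (x - ax)
            inside &= orient * cross >= 0.0
        return inside

    def area(self):
        return math.sqrt(3.0) / 4.0 * self.side**2

    def bounds(self):
        v = self.vertices
        return (v[:, 0].min(), v[:, 0].max(), v[:, 1].min(), v[:, 1].max())


def _polygon_orientation(v):
    s = 0.0
    n = len(v)
    for i in range(n):
        ax, ay = v[i]
        bx, by = v[(i + 1) % n]
        s += ax * by - bx * ay
    return 1.0 if s >= 0 else -1.0


@dataclass(frozen=True)
class TriangleLattice:
    """Hexagonal arrangement of equilateral triangles on a rectangular unit
    cell: one full triangle in the centre and a quarter triangle in each
    corner (all with the same orientation).

    ``cell`` is the (Lx, Ly) rectangular unit-cell size; for a true hexagonal
    lattice Lx/Ly ~= sqrt(3).  The cell spans [0, Lx) x [0, Ly).
    """

    side: float
    cell: tuple[float, float]
    vertex_angles: tuple[float, float, float] = (30.0, 150.0, 270.0)

    def contains(self, x, y):
        lx, ly = self.cell
        xm = np.mod(x, lx)
        ym = np.mod(y, ly)
        centres = [
            (lx / 2, ly / 2),
            (0.0, 0.0),
            (lx, 0.0),
            (0.0, ly),
            (lx, ly),
        ]
        inside = np.zeros(np.broadcast(np.asarray(xm), np.asarray(ym)).shape, bool)
        for c in centres:
            tri = Triangle(self.side, centre=c, vertex_angles=self.vertex_angles)
            inside |= tri.contains(xm, ym)
        return inside

    def area(self):
        # centre triangle + four quarter-triangle corners = two triangles/cell
        return 2.0 * math.sqrt(3.0) / 4.0 * self.side**2

    def bounds(self):
        return None  # fills its periodic cell


@dataclass(frozen=True)
class StripeArray:
    """Infinite stripes along x, repeating in y with the given period.

    One stripe occupies ``0 <= y mod period < width``; the remainder of the
    period is the non-magnetic gap.  Used for exchange-biased microstripe
    arrays whose magnetization is set perpendicular to the stripe axis.
    """

    width: float
    period: float

    def contains(self, x, y):
        del x
        return np.mod(y, self.period) < self.width

    def area(self):
        return None  # infinite; per-period area is width * Lx of the grid

    def bounds(self):
        return None


@dataclass(frozen=True)
class Oval:
    """Asymmetric oval: convex hull of two circles of different radii.

    The outline consists of two circular arcs (tip radius < base radius)
    joined by their common tangents, inside a bounding box of
    ``length x height``.  The base arc is on the -x side, the tip arc on the
    +x side; the element is centred at ``centre``.
    """

    length: float = 26e-6
    height: float = 21e-6
    tip_radius: float = 6e-6
    base_radius: float = 10.5e-6
    centre: tuple[float, float] = (0.0, 0.0)
    _hull: object = field(default=None, compare=False, repr=False)

    def __post_init__(self):
        if self.tip_radius >= self.base_radius:
            raise GeometryError("tip_radius must be smaller than base_radius")
        if 2 * self.base_radius > self.height + 1e-12:
            raise GeometryError("base circle exceeds the bounding-box height")
        cx, cy = self.centre
        xb = cx - self.length / 2 + self.base_radius
        xt = cx + self.length / 2 - self.tip_radius
        base = shapely.Point(xb, cy).buffer(self.base_radius, quad_segs=256)
        tip = shapely.Point(xt, cy).buffer(self.tip_radius, quad_segs=256)
        object.__setattr__(self, "_hull", base.union(tip).convex_hull)

    def contains(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return shapely.contains_xy(self._hull, x, y)

    def area(self):
        return self._hull.area

    def bounds(self):
        cx, cy = self.centre
        return (
            cx - self.length / 2,
            cx + self.length / 2,
            cy - self.height / 2,
            cy + self.height / 2,
        )
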