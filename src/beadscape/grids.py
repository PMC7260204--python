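"""Magnetization vector fields of the parent structure.

A :class:`MagnetizationGrid` holds the discretised magnetization M_p (A/m) of
the patterned film on a regular cell grid.  Grids are read from text OVF
1.0/2.0 files as emitted by micromagnetic solvers (OOMMF, mumax), or produced
synthetically as uniformly saturated shape masks standing in for the
near-saturated in-field states of real elements.

Coordinate convention: cell-centred, 0-based indices; x/y in-plane, z
out-of-plane; ``origin`` is the position (metres) of the centre of cell
(0, 0, 0).  For parent films the structure top surface sits at z = 0, so cell
centres have negative z.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import FormatError, GeometryError

__all__ = [
    "MagnetizationGrid",
    "read_ovf",
    "write_ovf",
    "synth_state",
    "downsample",
    "rotate_state",
]


@dataclass
class MagnetizationGrid:
    """Discretised magnetization M_p on a regular 3-D cell grid.

    Attributes
    ----------
    M : ndarray, shape (nz, ny, nx, 3)
        Magnetization vectors, A/m.  Cells outside the structure are zero.
    cell_size : (dx, dy, dz)
        Cell edge lengths, metres.
    origin : (x0, y0, z0)
        Position of the centre of cell (0, 0, 0), metres.
    Ms : float
        Saturation magnetization, A/m.
    periodic : (bool, bool)
        Whether the grid repeats along x and y.
    n_images : (int, int)
        Image repetitions per side used in potential summation for each
        periodic axis.
    """

    M: np.ndarray
    cell_size: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    Ms: float = None
    periodic: tuple[bool, bool] = (False, False)
    n_images: tuple[int, int] = (0, 0)

    def __post_init__(self):
        self.M = np.asarray(self.M, dtype=float)
        if self.M.ndim != 4 or self.M.shape[-1] != 3:
            raise ValueError("M must have shape (nz, ny, nx, 3)")
        if any(c <= 0 for c in self.cell_size):
            raise ValueError("cell_size must be strictly positive")
        if self.Ms is None:
            norms = np.linalg.norm(self.M, axis=-1)
            self.Ms = float(norms.max()) if norms.size else 0.0
        norms = np.linalg.norm(self.M, axis=-1)
        if self.Ms > 0 and norms.max() > self.Ms * (1 + 1e-6):
            raise ValueError("|M| exceeds Ms")

    # -- basic geometry -------------------------------------------------
    @property
    def n_cells(self):
        nz, ny, nx, _ = self.M.shape
        return (nx, ny, nz)

    @property
    def extent(self):
        """In-plane period lengths (Lx, Ly) covered by the cells."""
        nx, ny, _ = self.n_cells
        return (nx * self.cell_size[0], ny * self.cell_size[1])

    def cell_coords(self):
        """1-D arrays of cell-centre coordinates (x, y, z)."""
        nx, ny, nz = self.n_cells
        dx, dy, dz = self.cell_size
        x0, y0, z0 = self.origin
        return (
            x0 + dx * np.arange(nx),
            y0 + dy * np.arange(ny),
            z0 + dz * np.arange(nz),
        )

    @property
    def cell_volume(self):
        dx, dy, dz = self.cell_size
        return dx * dy * dz

    def active_cells(self):
        """Positions (nc, 3) and vectors (nc, 3) of magnetised cells."""
        x, y, z = self.cell_coords()
        zz, yy, xx = np.meshgrid(z, y, x, indexing="ij")
        flat_m = self.M.reshape(-1, 3)
        mask = np.any(flat_m != 0.0, axis=1)
        pos = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])[mask]
        return pos, flat_m[mask]

    def moment(self):
        """Total magnetic moment sum(M dV), A m^2 (3-vector)."""
        return self.M.reshape(-1, 3).sum(axis=0) * self.cell_volume

    def is_uniform(self):
        """True if all magnetised cells share one magnetization vector."""
        _, m = self.active_cells()
        if len(m) == 0:
            return True
        return bool(np.all(np.abs(m - m[0]) <= 1e-9 * np.linalg.norm(m[0])))


# ---------------------------------------------------------------------------
# OVF I/O (text OVF 1.0 / 2.0, rectangular meshes only)
# ---------------------------------------------------------------------------

_HEADER_RE = re.compile(r"^#\s*([A-Za-z ]+?)\s*:\s*(.*?)\s*$")


def read_ovf(path):
    """Read a text OVF 1.0/2.0 file into a :class:`MagnetizationGrid`.

    Values are scaled to A/m using ``valuemultiplier`` (OVF 1.0).  Binary
    segments, irregular meshes and valuedim != 3 are rejected.
    """
    headers = {}
    data_rows = []
    in_data = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = _HEADER_RE.match(line)
                if not m:
                    continue
                key = m.group(1).strip().lower()
                val = m.group(2)
                if key == "begin" and val.lower().startswith("data"):
                    kind = val.lower()
                    if "binary" in kind:
                        raise FormatError(
                            f"line {lineno}: binary OVF data is not supported ({line!r})"
                        )
                    in_data = True
                elif key == "end" and val.lower().startswith("data"):
                    in_data = False
                else:
                    headers[key] = val
            elif in_data:
                data_rows.append([float(v) for v in line.split()])

    def geth(key, cast=float, required=True, default=None):
        if key not in headers:
            if required:
                raise FormatError(f"missing OVF header line '# {key}: ...'")
            return default
        try:
            return cast(headers[key])
        except ValueError as exc:
            raise FormatError(f"bad OVF header '# {key}: {headers[key]}'") from exc

    meshtype = headers.get("meshtype", "rectangular").lower()
    if meshtype != "rectangular":
        raise FormatError(f"unsupported OVF header '# meshtype: {meshtype}'")
    valuedim = geth("valuedim", int, required=False, default=3)
    if valuedim != 3:
        raise FormatError(f"unsupported OVF header '# valuedim: {valuedim}'")

    nx = geth("xnodes", int)
    ny = geth("ynodes", int)
    nz = geth("znodes", int)
    dx = geth("xstepsize")
    dy = geth("ystepsize")
    dz = geth("zstepsize")
    meshunit = headers.get("meshunit", "m").strip()
    unit_scale = {"m": 1.0, "nm": 1e-9, "um": 1e-6, "µm": 1e-6}.get(meshunit)
    if unit_scale is None:
        raise FormatError(f"unsupported OVF header '# meshunit: {meshunit}'")
    mult = geth("valuemultiplier", float, required=False, default=1.0)

    x0 = geth("xbase", required=False, default=dx / 2) * unit_scale
    y0 = geth("ybase", required=False, default=dy / 2) * unit_scale
    z0 = geth("zbase", required=False, default=dz / 2) * unit_scale

    data = np.asarray(data_rows, dtype=float)
    if data.size != nx * ny * nz * 3 or (data.ndim == 2 and data.shape[1] != 3):
        raise FormatError(
            f"OVF data block has {data.size} values, expected {nx * ny * nz * 3}"
        )
    M = (data * mult).reshape(nz, ny, nx, 3)
    return MagnetizationGrid(
        M=M,
        cell_size=(dx * unit_scale, dy * unit_scale, dz * unit_scale),
        origin=(x0, y0, z0),
    )


def write_ovf(path, grid, title="beadscape magnetization"):
    """Write a grid as a text OVF 2.0 file (A/m, metres)."""
    nx, ny, nz = grid.n_cells
    dx, dy, dz = grid.cell_size
    x0, y0, z0 = grid.origin
    with open(path, "w") as fh:
        fh.write("# OOMMF OVF 2.0\n# Segment count: 1\n# Begin: Segment\n")
        fh.write("# Begin: Header\n")
        fh.write(f"# Title: {title}\n")
        fh.write("# meshtype: rectangular\n# meshunit: m\n")
        fh.write(f"# xbase: {x0:.12e}\n# ybase: {y0:.12e}\n# zbase: {z0:.12e}\n")
        fh.write(f"# xstepsize: {dx:.12e}\n# ystepsize: {dy:.12e}\n# zstepsize: {dz:.12e}\n")
        fh.write(f"# xnodes: {nx}\n# ynodes: {ny}\n# znodes: {nz}\n")
        fh.write("# valuedim: 3\n# valueunits: A/m A/m A/m\n")
        fh.write("# End: Header\n# Begin: Data Text\n")
        for row in grid.M.reshape(-1, 3):
            fh.write(f"{row[0]:.12e} {row[1]:.12e} {row[2]:.12e}\n")
        fh.write("# End: Data Text\n# End: Segment\n")


# ---------------------------------------------------------------------------
# Synthetic near-saturated states
# ---------------------------------------------------------------------------


def synth_state(
    geometry,
    direction,
    Ms,
    n_cells,
    cell_size,
    origin=None,
    periodic=(False, False),
    n_images=(0, 0),
):
    """Uniformly saturated shape-mask state: M = Ms * direction inside the
    geometry footprint, zero outside.

    Stands in for the near-saturated in-field states of soft-magnetic
    elements under a strong applied field.

    Parameters
    ----------
    geometry : shape object from :mod:`beadscape.geometry`
    direction : unit 3-vector of the magnetization direction
    Ms : saturation magnetization, A/m
    n_cells : (nx, ny, nz)
    cell_size : (dx, dy, dz), metres
    origin : centre of cell (0,0,0); default centres the grid in xy and puts
        the film top surface at z = 0.
    """
    direction = np.asarray(direction, dtype=float)
    if abs(np.linalg.norm(direction) - 1.0) > 1e-9:
        raise ValueError("|direction| must be 1")
    nx, ny, nz = n_cells
    dx, dy, dz = cell_size
    if origin is None:
        origin = (-(nx - 1) / 2 * dx, -(ny - 1) / 2 * dy, -nz * dz + dz / 2)

    x = origin[0] + dx * np.arange(nx)
    y = origin[1] + dy * np.arange(ny)
    xx, yy = np.meshgrid(x, y, indexing="xy")  # (ny, nx)
    mask = geometry.contains(xx, yy)

    # a shape spilling over a non-periodic grid edge is an error unless the
    # grid is a window fully inside the shape (uniform-film limit)
    b = geometry.bounds() if hasattr(geometry, "bounds") else None
    if b is not None and not bool(np.all(mask)):
        xmin, xmax, ymin, ymax = b
        half = (dx / 2, dy / 2)
        if not periodic[0] and (xmin < x[0] - half[0] - 1e-12 or xmax > x[-1] + half[0] + 1e-12):
            raise GeometryError("shape exceeds grid extent along x")
        if not periodic[1] and (ymin < y[0] - half[1] - 1e-12 or ymax > y[-1] + half[1] + 1e-12):
            raise GeometryError("shape exceeds grid extent along y")
    M = np.zeros((nz, ny, nx, 3))
    M[:, mask, :] = Ms * direction
    return MagnetizationGrid(
        M=M,
        cell_size=tuple(cell_size),
        origin=tuple(origin),
        Ms=Ms,
        periodic=tuple(periodic),
        n_images=tuple(n_images),
    )


# ---------------------------------------------------------------------------
# Grid transforms
# ---------------------------------------------------------------------------


def downsample(grid, factor):
    """Average the magnetization over ``factor x factor`` xy blocks.

    Non-dividing grids are padded with zero-magnetization (vacuum) cells at
    the high-index edge before averaging.  The total magnetic moment
    sum(M dV) is conserved exactly.
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return replace(grid, M=grid.M.copy())
    nz, ny, nx, _ = grid.M.shape
    pad_x = (-nx) % factor
    pad_y = (-ny) % factor
    M = grid.M
    if pad_x or pad_y:
        M = np.pad(M, ((0, 0), (0, pad_y), (0, pad_x), (0, 0)))
    nyp, nxp = ny + pad_y, nx + pad_x
    M = M.reshape(nz, nyp // factor, factor, nxp // factor, factor, 3)
    Mc = M.mean(axis=(2, 4))
    dx, dy, dz = grid.cell_size
    x0, y0, z0 = grid.origin
    return MagnetizationGrid(
        M=Mc,
        cell_size=(dx * factor, dy * factor, dz),
        origin=(x0 + (factor - 1) / 2 * dx, y0 + (factor - 1) / 2 * dy, z0),
        Ms=grid.Ms,
        periodic=grid.periodic,
        n_images=grid.n_images,
    )


def rotate_state(grid, angle_deg):
    """Rotate a circularly symmetric state about the grid centre.

    Cell positions are resampled nearest-neighbour and the magnetization
    vectors are rotated in-plane by the same angle, so that a uniformly
    magnetised circular element at field angle 0 maps exactly onto the state
    at field angle ``angle_deg``.  Requires a square grid (nx == ny); the
    caller is responsible for a circularly symmetric footprint.
    """
    nx, ny, nz = grid.n_cells
    if nx != ny:
        raise GeometryError("rotate_state requires nx == ny")
    theta = np.radians(angle_deg)
    c, s = np.cos(theta), np.sin(theta)
    # right-angle rotations are exact lattice maps: snap the matrix entries
    if abs(c - round(c)) < 1e-12:
        c = float(round(c))
    if abs(s - round(s)) < 1e-12:
        s = float(round(s))
    n = nx
    centre = (n - 1) / 2
    jj, ii = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")  # (y, x)
    xr = ii - centre
    yr = jj - centre
    # source index = inverse rotation of the target cell offset
    xs = c * xr + s * yr + centre
    ys = -s * xr + c * yr + centre
    isrc = np.rint(xs).astype(int)
    jsrc = np.rint(ys).astype(int)
    valid = (isrc >= 0) & (isrc < n) & (jsrc >= 0) & (jsrc < n)
    isrc = np.clip(isrc, 0, n - 1)
    jsrc = np.clip(jsrc, 0, n - 1)
    out = np.zeros_like(grid.M)
    src = grid.M[:, jsrc, isrc, :]  # (nz, ny, nx, 3)
    src[:, ~valid, :] = 0.0
    out[..., 0] = c * src[..., 0] - s * src[..., 1]
    out[..., 1] = s * src[..., 0] + c * src[..., 1]
    out[..., 2] = src[..., 2]
    return replace(grid, M=out)
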