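"""Bead potential-energy maps from the parent magnetization.

By the magnetostatic reciprocal theorem the bead--structure interaction
energy can be written as an integral of the parent magnetization against the
bead's dipole stray field, avoiding any computation of the parent's own
stray field:

    U(s) = -mu0 * sum_cells  M_p(c) . [ 2 * H_mb(r_c - s) ] * dV

The position-independent -mu0 M_p.H_ext term and the integration constant are
dropped (only the gradient of U matters).  The factor 2 is the reciprocity
factor of the mutual-energy formulation.

Periodic structures are handled by minimum-image wrapping of the in-plane
displacement plus summation over +/- n_images repetitions per side, which
makes the resulting map exactly periodic.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .dipole import MU0, bead_moment
from .errors import ConfigurationError, SingularityError

__all__ = [
    "PotentialGridSpec",
    "PotentialMap",
    "compute_potential",
    "potential_sequence",
]


@dataclass
class PotentialGridSpec:
    """Node grid on which the bead potential U is sampled.

    The z coordinate is the bead-centre height relative to its rest height:
    z = 0 means the bead centre sits r_mb above the substrate surface.
    Nodes are vertex-centred over ``x_range``/``y_range``; on periodic axes
    the upper bound is the period (the seam node is not duplicated).
    """

    x_range: tuple[float, float]
    y_range: tuple[float, float]
    n_nodes: tuple[int, int]
    z_layers: np.ndarray
    periodic: tuple[bool, bool] = (False, False)
    n_images: tuple[int, int] = (0, 0)

    def __post_init__(self):
        self.z_layers = np.asarray(self.z_layers, dtype=float)
        nx, ny = self.n_nodes
        if nx < 3 or ny < 3:
            raise ValueError("n_nodes must be >= 3 per in-plane axis")
        if self.z_layers.ndim != 1 or len(self.z_layers) < 1:
            raise ValueError("z_layers must be a non-empty 1-D array")
        if np.any(np.diff(self.z_layers) <= 0):
            raise ValueError("z_layers must be strictly increasing")

    @property
    def lengths(self):
        return (self.x_range[1] - self.x_range[0], self.y_range[1] - self.y_range[0])

    @property
    def spacing(self):
        """In-plane node spacings (dx, dy)."""
        nx, ny = self.n_nodes
        lx, ly = self.lengths
        dx = lx / nx if self.periodic[0] else lx / (nx - 1)
        dy = ly / ny if self.periodic[1] else ly / (ny - 1)
        return (dx, dy)

    def node_coords(self):
        """1-D node coordinate arrays (x, y, z)."""
        nx, ny = self.n_nodes
        dx, dy = self.spacing
        x = self.x_range[0] + dx * np.arange(nx)
        y = self.y_range[0] + dy * np.arange(ny)
        return x, y, self.z_layers.copy()

    @property
    def shape(self):
        """(nz, ny, nx) array shape of one potential slab."""
        return (len(self.z_layers), self.n_nodes[1], self.n_nodes[0])


@dataclass
class PotentialMap:
    """Potential U (joules) sampled on (state, nz, ny, nx)."""

    U: np.ndarray
    spec: PotentialGridSpec
    times: np.ndarray = None
    angles: np.ndarray = None
    frequency: float = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.U = np.asarray(self.U, dtype=float)
        if self.U.ndim != 4:
            raise ValueError("U must have shape (n_state, nz, ny, nx)")
        if not np.all(np.isfinite(self.U)):
            raise ValueError("potential map contains non-finite values")

    @property
    def n_states(self):
        return self.U.shape[0]


# ---------------------------------------------------------------------------
# Pairwise summation kernels
# ---------------------------------------------------------------------------


def _image_offsets(grid, spec):
    """Image shift vectors implied by the periodic flags of grid and spec."""
    per_x = grid.periodic[0] or spec.periodic[0]
    per_y = grid.periodic[1] or spec.periodic[1]
    lx, ly = grid.extent
    nix = max(grid.n_images[0], spec.n_images[0]) if per_x else 0
    niy = max(grid.n_images[1], spec.n_images[1]) if per_y else 0
    kx = range(-nix, nix + 1)
    ky = range(-niy, niy + 1)
    periods = (lx if per_x else None, ly if per_y else None)
    return [(i * lx, j * ly) for i, j in itertools.product(kx, ky)], periods


def _node_positions(spec, r_mb):
    """Bead-centre lab positions (nn, 3) in slab flattening order (z, y, x)."""
    x, y, z = spec.node_coords()
    if z[0] < -r_mb / 2 - 1e-15:
        raise ValueError(
            "lowest z layer must stay at or above -r_mb/2 "
            "(bead centre at least r_mb/2 above the surface)"
        )
    zz, yy, xx = np.meshgrid(z + r_mb, y, x, indexing="ij")
    return np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])


def _min_distance_check(r2min, cell_size):
    h = max(cell_size)
    if r2min < (0.25 * h) ** 2:
        raise SingularityError(
            "bead centre coincides with a parent cell centre; "
            "lowest z layer is too close to the film"
        )


def stray_vector_field(grid, spec, r_mb, block_bytes=2 ** 27):
    """Reduced stray-field sum w(s) = sum_c dV K(r_c - s) M_c  (nn, 3).

    K(r) = (3 rhat rhat^T - I) / (4 pi |r|^3) is the dipole kernel, so the
    potential for a bead of moment m is U(s) = -2 mu0 w(s) . m.  One pass
    serves every field state of a structure whose magnetization is fixed.
    """
    cells, Mc = grid.active_cells()
    nodes = _node_positions(spec, r_mb)
    offsets, periods = _image_offsets(grid, spec)
    w = np.zeros((len(nodes), 3))
    if len(cells) == 0:
        return w
    dV = grid.cell_volume
    block = max(1, int(block_bytes // (len(cells) * 3 * 8)))
    for a in range(0, len(nodes), block):
        nb = nodes[a : a + block]
        d0 = cells[None, :, :] - nb[:, None, :]
        for ax, L in enumerate(periods):
            if L is not None:
                # floor-form wrap: maps d and d +/- L identically even at
                # the exact half-period boundary
                d0[..., ax] -= L * np.floor(d0[..., ax] / L + 0.5)
        acc = np.zeros((len(nb), 3))
        for ox, oy in offsets:
            d = d0 + np.array([ox, oy, 0.0])
            r2 = np.einsum("bci,bci->bc", d, d)
            _min_distance_check(r2.min(), grid.cell_size)
            inv_r = 1.0 / np.sqrt(r2)
            inv_r3 = inv_r**3
            mdotr = np.einsum("bci,ci->bc", d, Mc) * inv_r * inv_r
            # K M = [3 u (M.u) - M] / (4 pi r^3)  with u = d/r
            coef = 3.0 * mdotr * inv_r3
            acc += np.einsum("bc,bci->bi", coef, d)
            acc -= np.einsum("bc,ci->bi", inv_r3, Mc)
        w[a : a + block] = acc
    return w * (dV / (4.0 * math.pi))


def stray_tensor_field(grid, spec, r_mb, block_bytes=2 ** 27):
    """Reduced stray-tensor sum G(s) = sum_c dV K(r_c - s)  (nn, 6).

    Valid for uniformly magnetised structures: with M = Ms uhat and a bead
    moment m = |m| uhat along the same unit vector, U(s) =
    -2 mu0 Ms |m| uhat^T G(s) uhat.  Component order (xx, yy, zz, xy, xz, yz).
    """
    cells, _ = grid.active_cells()
    nodes = _node_positions(spec, r_mb)
    offsets, periods = _image_offsets(grid, spec)
    G = np.zeros((len(nodes), 6))
    if len(cells) == 0:
        return G
    dV = grid.cell_volume
    block = max(1, int(block_bytes // (len(cells) * 3 * 8)))
    for a in range(0, len(nodes), block):
        nb = nodes[a : a + block]
        d0 = cells[None, :, :] - nb[:, None, :]
        for ax, L in enumerate(periods):
            if L is not None:
                # floor-form wrap: maps d and d +/- L identically even at
                # the exact half-period boundary
                d0[..., ax] -= L * np.floor(d0[..., ax] / L + 0.5)
        acc = np.zeros((len(nb), 6))
        for ox, oy in offsets:
            d = d0 + np.array([ox, oy, 0.0])
            r2 = np.einsum("bci,bci->bc", d, d)
            _min_distance_check(r2.min(), grid.cell_size)
            inv_r2 = 1.0 / r2
            inv_r3 = inv_r2 / np.sqrt(r2)
            f = 3.0 * inv_r3 * inv_r2
            acc[:, 0] += (f * d[..., 0] * d[..., 0] - inv_r3).sum(axis=1)
            acc[:, 1] += (f * d[..., 1] * d[..., 1] - inv_r3).sum(axis=1)
            acc[:, 2] += (f * d[..., 2] * d[..., 2] - inv_r3).sum(axis=1)
            acc[:, 3] += (f * d[..., 0] * d[..., 1]).sum(axis=1)
            acc[:, 4] += (f * d[..., 0] * d[..., 2]).sum(axis=1)
            acc[:, 5] += (f * d[..., 1] * d[..., 2]).sum(axis=1)
        G[a : a + block] = acc
    return G * (dV / (4.0 * math.pi))


def _quadratic_form(G, u):
    ux, uy, uz = u
    return (
        G[:, 0] * ux * ux
        + G[:, 1] * uy * uy
        + G[:, 2] * uz * uz
        + 2.0 * (G[:, 3] * ux * uy + G[:, 4] * ux * uz + G[:, 5] * uy * uz)
    )


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def compute_potential(grid, bead, H_ext, spec):
    """Single-state potential slab U (nz, ny, nx) in joules.

    ``H_ext`` is the external field in A/m; the bead moment follows it.
    """
    m = bead_moment(bead, H_ext)
    w = stray_vector_field(grid, spec, bead.r_mb)
    U = -2.0 * MU0 * (w @ m)
    return U.reshape(spec.shape)


def potential_sequence(source, bead, field_seq, spec, follow_field=None):
    """Ordered stack of potential slabs, one per field state.

    ``source`` is either a single :class:`MagnetizationGrid` or a list with
    one grid per field state.

    For a single grid, ``follow_field`` selects the state model:

    * ``True`` -- the structure is re-magnetised uniformly along each field
      direction (synthetic in-field states of soft elements; requires a
      uniformly magnetised grid).  Rotating sequences of circular elements
      are the same thing: rotating the state and the field together equals
      rotating the magnetization direction over the fixed mask.
    * ``False`` -- the structure magnetization is fixed for every state
      (exchange-biased elements); only the bead moment follows the field.

    Defaults to ``True`` for a uniform grid under a rotating field, else
    ``False``.
    """
    fields_T = field_seq.state_fields()  # (ns, 3), tesla
    ns = len(fields_T)

    if isinstance(source, (list, tuple)):
        if len(source) != ns:
            raise ConfigurationError(
                f"{len(source)} magnetization states for {ns} field states"
            )
        slabs = [
            compute_potential(g, bead, B / MU0, spec) for g, B in zip(source, fields_T)
        ]
        U = np.stack(slabs)
    else:
        grid = source
        if follow_field is None:
            follow_field = field_seq.mode == "rotating" and grid.is_uniform()
        if follow_field:
            if not grid.is_uniform():
                raise ConfigurationError(
                    "follow_field=True requires a uniformly magnetised grid"
                )
            G = stray_tensor_field(grid, spec, bead.r_mb)
            U = np.empty((ns,) + spec.shape)
            for k, B in enumerate(fields_T):
                Bn = np.linalg.norm(B)
                if Bn == 0:
                    U[k] = 0.0
                    continue
                u = B / Bn
                mmag = bead.chi * bead.volume * Bn / MU0
                q = _quadratic_form(G, u)
                U[k] = (-2.0 * MU0 * grid.Ms * mmag * q).reshape(spec.shape)
        else:
            w = stray_vector_field(grid, spec, bead.r_mb)
            U = np.empty((ns,) + spec.shape)
            for k, B in enumerate(fields_T):
                m = bead_moment(bead, B / MU0)
                U[k] = (-2.0 * MU0 * (w @ m)).reshape(spec.shape)

    angles = field_seq.sample_angles() if field_seq.mode == "rotating" else None
    return PotentialMap(
        U=U,
        spec=spec,
        times=field_seq.sample_times(),
        angles=angles,
        frequency=field_seq.frequency,
    )
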