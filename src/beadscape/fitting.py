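"""Compression of potential maps into a continuously evaluable U(t, s).

Time: each node's time series is fitted with a truncated Fourier series of
order N (least squares on the sample grid).  Space: around every grid node a
3x3x3 (or 5x5x5) submatrix window is fitted, per Fourier coefficient, with
the 11-term polynomial basis

    p(s) = (1, x, y, z, xy, xz, yz, xyz, x^2, y^2, z^2)

in submatrix-local coordinates (centred on the node, scaled by the grid
spacing).  The potential is then

    U(t, s) = F1(t)^T A p(s) + F2(t)^T B p(s)

with F1 = (1, cos wt, ..., cos Nwt), F2 = (0, sin wt, ..., sin Nwt), and the
magnetic force is the analytic negative gradient of the active submatrix
polynomial.  Submatrix coefficient matrices are assembled lazily from the
stored Fourier coefficient maps (the spatial fit is a fixed linear operator
per window pattern) and cached per node.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, FitRankError

__all__ = [
    "fit_time",
    "concat_states",
    "fit_space",
    "fit_potential",
    "FittedPotential",
    "eval_U",
    "eval_force",
]


# ---------------------------------------------------------------------------
# Time fit
# ---------------------------------------------------------------------------


def fourier_design(times, N, omega):
    """Design matrix [cos(k w t) | sin(k w t), k=1..N] of shape (nt, 2N+1)."""
    t = np.asarray(times, dtype=float)
    k = np.arange(N + 1)
    phase = omega * t[:, None] * k[None, :]
    return np.hstack([np.cos(phase), np.sin(phase[:, 1:])])


def fit_time(U, times, N, omega):
    """Least-squares Fourier coefficients per node.

    Parameters
    ----------
    U : ndarray (nt, ...) -- time-sampled potential (or any signal).
    times : sample times (s), one period.
    N : Fourier order.
    omega : angular frequency 2 pi f (rad/s).

    Returns
    -------
    A : ndarray (N+1, ...) cosine coefficients (row 0 is the mean term).
    B : ndarray (N+1, ...) sine coefficients (row 0 is identically zero).

    Uniformly sampled square waves built by state concatenation may have
    exactly 2N samples; the degenerate Nyquist sine column is then handled
    by the minimum-norm solution.  Fewer than 2N samples raises
    :class:`FitRankError`.
    """
    U = np.asarray(U, dtype=float)
    nt = U.shape[0]
    if nt < 2 * N:
        raise FitRankError(f"{nt} time samples cannot determine a Fourier fit of order {N}")
    D = fourier_design(times, N, omega)
    flat = U.reshape(nt, -1)
    coef, *_ = np.linalg.lstsq(D, flat, rcond=None)
    A = coef[: N + 1].reshape((N + 1,) + U.shape[1:])
    Bpart = coef[N + 1 :].reshape((N,) + U.shape[1:])
    B = np.concatenate([np.zeros((1,) + U.shape[1:]), Bpart], axis=0)
    return A, B


def concat_states(slabs, copies_per_state):
    """Repeat each state slab ``copies_per_state`` times along the time axis.

    Emulates square-wave switching sequences before the Fourier fit:
    ns states x c copies -> (ns*c) uniformly spaced time samples in state
    order.
    """
    if copies_per_state < 1:
        raise ValueError("copies_per_state must be >= 1")
    slabs = np.asarray(slabs)
    return np.repeat(slabs, copies_per_state, axis=0)


# ---------------------------------------------------------------------------
# Spatial fit
# ---------------------------------------------------------------------------


def _poly_design(xo, yo, zo, with_z=True):
    """Design matrix of the 11-term basis over the local offsets.

    Rows iterate the window in (z, y, x) order to match slab flattening.
    """
    Z, Y, X = np.meshgrid(zo, yo, xo, indexing="ij")
    x, y, z = X.ravel(), Y.ravel(), Z.ravel()
    one = np.ones_like(x)
    if with_z:
        cols = [one, x, y, z, x * y, x * z, y * z, x * y * z, x * x, y * y, z * z]
    else:
        cols = [one, x, y, x * y, x * x, y * y]
    return np.column_stack(cols)


def _poly_eval_row(x, y, z, with_z=True):
    if with_z:
        return np.array(
            [1.0, x, y, z, x * y, x * z, y * z, x * y * z, x * x, y * y, z * z]
        )
    return np.array([1.0, x, y, x * y, x * x, y * y])


def _poly_grad_rows(x, y, z, with_z=True):
    """d p / d(x, y, z) in local coordinates, shape (3, n_terms)."""
    if with_z:
        return np.array(
            [
                [0.0, 1.0, 0.0, 0.0, y, z, 0.0, y * z, 2 * x, 0.0, 0.0],
                [0.0, 0.0, 1.0, 0.0, x, 0.0, z, x * z, 0.0, 2 * y, 0.0],
                [0.0, 0.0, 0.0, 1.0, 0.0, x, y, x * y, 0.0, 0.0, 2 * z],
            ]
        )
    return np.array(
        [
            [0.0, 1.0, 0.0, y, 2 * x, 0.0],
            [0.0, 0.0, 1.0, x, 0.0, 2 * y],
        ]
    )


def _axis_window(i, n, hw, periodic):
    """Window indices and local offsets for a submatrix centred at index i."""
    offs = np.arange(-hw, hw + 1)
    if periodic:
        return (i + offs) % n, offs.astype(float)
    lo = min(max(i - hw, 0), n - (2 * hw + 1))
    idx = np.arange(lo, lo + 2 * hw + 1)
    return idx, (idx - i).astype(float)


@dataclass
class FittedPotential:
    """Fourier coefficient maps plus lazily assembled submatrix polynomials.

    A, B : ndarray (N+1, nz, ny, nx) -- cosine / sine coefficient maps.
    omega : angular drive frequency, rad/s.
    spec : the PotentialGridSpec of the fitted map.
    submatrix : window size per axis (3 or 5).
    """

    A: np.ndarray
    B: np.ndarray
    omega: float
    spec: object
    submatrix: int = 3

    def __post_init__(self):
        if self.submatrix not in (3, 5):
            raise ValueError("submatrix size must be 3 or 5")
        if not (np.all(np.isfinite(self.A)) and np.all(np.isfinite(self.B))):
            raise ValueError("non-finite Fourier coefficients")
        nz = self.A.shape[1]
        self.fit_z = nz >= 3
        if not self.fit_z and nz != 1:
            raise ValueError("z fitting needs >= 3 layers (or exactly 1 for 2-D maps)")
        self._coef_cache = {}
        self._design_cache = {}
        self.residuals = {}
        x, y, z = self.spec.node_coords()
        self._x0, self._y0 = x[0], y[0]
        self._dx, self._dy = self.spec.spacing
        self._z = z
        self._nx, self._ny = self.spec.n_nodes
        self._nz = len(z)
        self._lx, self._ly = self.spec.lengths
        self._k = np.arange(self.A.shape[0])
        # index of the z = 0 layer (bead resting height), nearest node
        self._iz0 = int(np.argmin(np.abs(z)))

    # -- submatrix bookkeeping -----------------------------------------
    @property
    def N(self):
        return self.A.shape[0] - 1

    def nearest_node(self, s, prev=None):
        """(iz, iy, ix) of the node nearest to position s.

        With ``prev`` given, axes stay on the previous centre until the
        position genuinely leaves its half-spacing cell (hysteresis
        tie-break, so the active submatrix changes only when the trajectory
        crosses a node boundary).
        """
        x, y, z = s
        ix = self._axis_index(x, self._x0, self._dx, self._nx, self.spec.periodic[0])
        iy = self._axis_index(y, self._y0, self._dy, self._ny, self.spec.periodic[1])
        iz = int(np.argmin(np.abs(self._z - z)))
        if prev is not None:
            pz, py, px = prev
            if self._within_half(x, px, self._x0, self._dx, self._nx, self.spec.periodic[0]):
                ix = px
            if self._within_half(y, py, self._y0, self._dy, self._ny, self.spec.periodic[1]):
                iy = py
            if abs(z - self._z[pz]) <= 0.5 * abs(
                self._z[min(pz + 1, self._nz - 1)] - self._z[max(pz - 1, 0)]
            ) / 2 + 1e-15:
                iz = pz
        return (iz, iy, ix)

    def _axis_index(self, v, v0, dv, n, periodic):
        i = int(math.floor((v - v0) / dv + 0.5))
        if periodic:
            return i % n
        if i < 0 or i > n - 1:
            if v < v0 - 0.75 * dv or v > v0 + (n - 1 + 0.75) * dv:
                raise DomainError("position outside the fitted extent")
            i = min(max(i, 0), n - 1)
        return i

    def _within_half(self, v, i, v0, dv, n, periodic):
        d = v - (v0 + i * dv)
        if periodic:
            L = n * dv
            d -= L * math.floor(d / L + 0.5)
        return abs(d) <= 0.5 * dv * (1 + 1e-9)

    def _window(self, centre):
        iz, iy, ix = centre
        hw = self.submatrix // 2
        xi, xo = _axis_window(ix, self._nx, hw, self.spec.periodic[0])
        yi, yo = _axis_window(iy, self._ny, hw, self.spec.periodic[1])
        if self.fit_z:
            zi, _ = _axis_window(iz, self._nz, hw, False)
            zvals = self._z[zi] - self._z[iz]
            sz = (self._z[zi[-1]] - self._z[zi[0]]) / (len(zi) - 1)
            zo = zvals / sz
        else:
            zi = np.array([iz])
            zo = np.array([0.0])
            sz = 1.0
        return xi, yi, zi, xo, yo, zo, sz

    def coefficients(self, centre):
        """Submatrix coefficient matrices (Asub, Bsub) of shape (N+1, n_terms)
        plus the local z scale, assembled lazily and cached."""
        cached = self._coef_cache.get(centre)
        if cached is not None:
            return cached
        xi, yi, zi, xo, yo, zo, sz = self._window(centre)
        key = (tuple(xo), tuple(yo), tuple(np.round(zo, 12)))
        P = self._design_cache.get(key)
        if P is None:
            D = _poly_design(xo, yo, zo, with_z=self.fit_z)
            # regular tensor-product windows keep the normal equations full
            # rank; a degenerate window would surface as a huge pinv residual
            P = np.linalg.pinv(D)
            self._design_cache[key] = (P, D)
        else:
            P, D = P
        Awin = self.A[:, zi[:, None, None], yi[None, :, None], xi[None, None, :]]
        Bwin = self.B[:, zi[:, None, None], yi[None, :, None], xi[None, None, :]]
        nterms = P.shape[0]
        Aw = Awin.reshape(self.A.shape[0], -1)
        Bw = Bwin.reshape(self.B.shape[0], -1)
        Asub = Aw @ P.T
        Bsub = Bw @ P.T
        res = max(
            float(np.abs(Asub @ D.T - Aw).max()),
            float(np.abs(Bsub @ D.T - Bw).max()),
        )
        if not (np.all(np.isfinite(Asub)) and np.all(np.isfinite(Bsub))):
            raise FitRankError(f"degenerate submatrix window at {centre}")
        self.residuals[centre] = res
        out = (Asub, Bsub, sz)
        self._coef_cache[centre] = out
        return out

    # -- evaluation -----------------------------------------------------
    def _local(self, s, centre, sz):
        iz, iy, ix = centre
        x, y, z = s
        dxl = x - (self._x0 + ix * self._dx)
        if self.spec.periodic[0]:
            L = self._nx * self._dx
            dxl -= L * math.floor(dxl / L + 0.5)
        dyl = y - (self._y0 + iy * self._dy)
        if self.spec.periodic[1]:
            L = self._ny * self._dy
            dyl -= L * math.floor(dyl / L + 0.5)
        dzl = z - self._z[iz]
        return dxl / self._dx, dyl / self._dy, dzl / sz

    def time_vectors(self, t):
        phase = self._k * (self.omega * t)
        return np.cos(phase), np.sin(phase)

    def eval_U(self, t, s, centre=None):
        """Potential U(t, s) in joules from the nearest-node submatrix."""
        if centre is None:
            centre = self.nearest_node(s)
        Asub, Bsub, sz = self.coefficients(centre)
        F1, F2 = self.time_vectors(t)
        c = F1 @ Asub + F2 @ Bsub
        xl, yl, zl = self._local(s, centre, sz)
        return float(c @ _poly_eval_row(xl, yl, zl, with_z=self.fit_z))

    def eval_force(self, t, s, centre=None):
        """Magnetic force F_m = -grad U (newtons, 3-vector)."""
        if centre is None:
            centre = self.nearest_node(s)
        Asub, Bsub, sz = self.coefficients(centre)
        F1, F2 = self.time_vectors(t)
        c = F1 @ Asub + F2 @ Bsub
        xl, yl, zl = self._local(s, centre, sz)
        g = _poly_grad_rows(xl, yl, zl, with_z=self.fit_z) @ c
        if self.fit_z:
            return -np.array([g[0] / self._dx, g[1] / self._dy, g[2] / sz])
        return -np.array([g[0] / self._dx, g[1] / self._dy, 0.0])

    def eval_Uc(self, c, s, centre, sz):
        xl, yl, zl = self._local(s, centre, sz)
        return float(c @ _poly_eval_row(xl, yl, zl, with_z=self.fit_z))

    @property
    def iz0(self):
        """Index of the z = 0 (resting-height) layer."""
        return self._iz0


def fit_space(A, B, omega, spec, submatrix=3):
    """Bundle Fourier coefficient maps into a :class:`FittedPotential`."""
    return FittedPotential(A=A, B=B, omega=omega, spec=spec, submatrix=submatrix)


def fit_potential(pmap, N, submatrix=3, copies_per_state=None):
    """Fourier + polynomial fit of a :class:`PotentialMap`.

    ``copies_per_state`` (switching sequences) repeats each slab before the
    time fit to emulate the square-wave drive.
    """
    U = pmap.U
    period = 1.0 / pmap.frequency
    omega = 2.0 * math.pi * pmap.frequency
    if copies_per_state is not None and copies_per_state > 1:
        U = concat_states(U, copies_per_state)
    nt = U.shape[0]
    times = period * np.arange(nt) / nt
    A, B = fit_time(U, times, N, omega)
    return fit_space(A, B, omega, pmap.spec, submatrix=submatrix)


def eval_U(fit, t, s):
    """Functional wrapper for :meth:`FittedPotential.eval_U`."""
    return fit.eval_U(t, s)


def eval_force(fit, t, s):
    """Functional wrapper for :meth:`FittedPotential.eval_force`."""
    return fit.eval_force(t, s)
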