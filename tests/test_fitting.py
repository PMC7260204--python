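"""Fourier-in-time and local-polynomial-in-space fitting of potential maps."""

import math

import numpy as np
import pytest

from beadscape import (
    DomainError,
    FitRankError,
    PotentialGridSpec,
    PotentialMap,
    concat_states,
    fit_potential,
    fit_space,
    fit_time,
)
from beadscape.fitting import FittedPotential, fourier_design


def make_spec(nx=9, ny=9, z=(-1e-6, 0.0, 1e-6, 2e-6), periodic=(False, False)):
    return PotentialGridSpec(
        x_range=(-4e-6, 4e-6), y_range=(-4e-6, 4e-6), n_nodes=(nx, ny),
        z_layers=np.array(z), periodic=periodic,
    )


def quadratic_map(spec, f=lambda X, Y, Z: 2 * X**2 + 3 * Y**2 - Z**2 + X * Y, n_states=4):
    """Map whose spatial dependence lies in the 11-term basis (local units)."""
    x, y, z = spec.node_coords()
    dx, dy = spec.spacing
    sz = z[1] - z[0]
    Z, Y, X = np.meshgrid(z / sz, y / dy, x / dx, indexing="ij")
    U0 = f(X, Y, Z) * 1e-18
    return PotentialMap(
        U=np.stack([U0] * n_states), spec=spec, frequency=1.0,
        times=np.arange(n_states) / n_states,
    )


class TestFitTime:
    def test_constant_signal_is_pure_dc(self):
        t = np.arange(8) / 8
        U = np.full((8, 5), 3.7)
        A, B = fit_time(U, t, N=3, omega=2 * math.pi)
        np.testing.assert_allclose(A[0], 3.7, rtol=1e-12)
        assert np.abs(A[1:]).max() < 1e-12 * 3.7
        assert np.abs(B).max() < 1e-12 * 3.7

    def test_single_harmonic_recovered(self):
        # U(t) = cos(w t) on 180 samples, order 30
        t = np.arange(180) / 180
        U = np.cos(2 * math.pi * t)[:, None]
        A, B = fit_time(U, t, N=30, omega=2 * math.pi)
        assert A[1, 0] == pytest.approx(1.0, abs=1e-10)
        mask = np.ones(31, bool)
        mask[1] = False
        assert np.abs(A[mask]).max() < 1e-10
        assert np.abs(B).max() < 1e-10

    def test_square_wave_matches_partial_sum_oracle(self):
        # two-state switching concatenated 100 + 100, order N = 100: the
        # least-squares fit must agree with the DFT partial sum (independent
        # oracle) both on and off the sample grid
        vals = np.array([1.0, -1.0])
        U = concat_states(vals[:, None], 100)  # (200, 1) square wave
        nt = 200
        t = np.arange(nt) / nt
        N = 100
        A, B = fit_time(U, t, N=N, omega=2 * math.pi)
        # oracle: rfft of the samples
        F = np.fft.rfft(U[:, 0]) / nt
        a_or = np.concatenate([[F[0].real], 2 * F[1:N].real, [F[N].real]])
        b_or = np.concatenate([[0.0], -2 * F[1:N].imag, [-F[N].imag]])
        tq = np.linspace(0, 1, 733)
        D = fourier_design(tq, N, 2 * math.pi)
        fit_vals = D @ np.concatenate([A[:, 0], B[1:, 0]])
        oracle_vals = D @ np.concatenate([a_or, b_or[1:]])
        np.testing.assert_allclose(fit_vals, oracle_vals, atol=1e-9)
        # reconstruction is exact at the sample points (complete basis at 2N)
        Ds = fourier_design(t, N, 2 * math.pi)
        np.testing.assert_allclose(Ds @ np.concatenate([A[:, 0], B[1:, 0]]), U[:, 0], atol=1e-9)

    def test_too_few_samples_raises(self):
        t = np.arange(10) / 10
        with pytest.raises(FitRankError):
            fit_time(np.ones((10, 2)), t, N=6, omega=2 * math.pi)


class TestConcatStates:
    def test_counts_and_order(self):
        s = np.arange(4).reshape(4, 1, 1, 1).astype(float)
        out = concat_states(s, 50)
        assert out.shape[0] == 200
        np.testing.assert_array_equal(out[:50, 0, 0, 0], 0.0)
        np.testing.assert_array_equal(out[50:100, 0, 0, 0], 1.0)
        out2 = concat_states(s[:2], 100)
        assert out2.shape[0] == 200

    def test_single_state_is_constant(self):
        out = concat_states(np.array([[2.0]]), 7)
        np.testing.assert_array_equal(out, 2.0)

    def test_bad_copies(self):
        with pytest.raises(ValueError):
            concat_states(np.ones((2, 1)), 0)


class TestFitSpace:
    def test_quadratic_map_recovered_exactly(self):
        spec = make_spec()
        pm = quadratic_map(spec)
        fit = fit_potential(pm, N=1)
        dx, dy = spec.spacing
        sz = spec.z_layers[1] - spec.z_layers[0]
        # force = -grad U with U = (2x^2 + 3y^2 - z^2 + xy) 1e-18, local units
        for s in [(1.3e-6, -2.1e-6, 0.4e-6), (0.0, 0.0, 0.0), (-3e-6, 1e-6, 1.2e-6)]:
            xl, yl, zl = s[0] / dx, s[1] / dy, s[2] / sz
            F = fit.eval_force(0.2, s)
            expect = -1e-18 * np.array(
                [(4 * xl + yl) / dx, (6 * yl + xl) / dy, -2 * zl / sz]
            )
            np.testing.assert_allclose(F, expect, rtol=1e-9, atol=1e-22)
        res = max(fit.residuals.values())
        assert res < 1e-12 * np.abs(pm.U).max()

    def test_constant_map_only_dc_term(self):
        spec = make_spec()
        x, y, z = spec.node_coords()
        U = np.full((2,) + spec.shape, 4.2e-18)
        pm = PotentialMap(U=U, spec=spec, frequency=1.0, times=np.array([0.0, 0.5]))
        fit = fit_potential(pm, N=0)
        A, _, _ = fit.coefficients((1, 4, 4))
        assert A[0, 0] == pytest.approx(4.2e-18, rel=1e-12)
        assert np.abs(A[0, 1:]).max() < 1e-12 * 4.2e-18

    def test_cubic_residual_shrinks_under_refinement(self):
        residuals = []
        for nx in (9, 17):
            spec = PotentialGridSpec(
                x_range=(-4e-6, 4e-6), y_range=(-4e-6, 4e-6), n_nodes=(nx, nx),
                z_layers=np.linspace(-1e-6, 2e-6, 4),
            )
            x, y, z = spec.node_coords()
            Z, Y, X = np.meshgrid(z, y, x, indexing="ij")
            U = (X / 4e-6) ** 3 * 1e-18
            pm = PotentialMap(U=U[None], spec=spec, frequency=1.0, times=np.array([0.0]))
            fit = fit_potential(pm, N=0)
            centre = (1, nx // 2, nx // 2)
            fit.coefficients(centre)
            residuals.append(fit.residuals[centre])
        assert residuals[0] > 0
        assert residuals[1] < residuals[0]

    def test_band_limited_space_time_model_reproduced(self, rng):
        # random coefficients in span{1, cos kwt, sin kwt} x 11-term basis
        spec = make_spec()
        N = 3
        x, y, z = spec.node_coords()
        dx, dy = spec.spacing
        sz = z[1] - z[0]
        Z, Y, X = np.meshgrid(z / sz, y / dy, x / dx, indexing="ij")
        basis = [np.ones_like(X), X, Y, Z, X * Y, X * Z, Y * Z, X * Y * Z, X**2, Y**2, Z**2]
        ca = rng.normal(size=(N + 1, 11)) * 1e-18
        cb = rng.normal(size=(N + 1, 11)) * 1e-18
        cb[0] = 0.0
        nt = 16
        times = np.arange(nt) / nt
        w = 2 * math.pi
        U = np.zeros((nt,) + spec.shape)
        for it, t in enumerate(times):
            F1 = np.cos(w * t * np.arange(N + 1))
            F2 = np.sin(w * t * np.arange(N + 1))
            for j, b in enumerate(basis):
                U[it] += (F1 @ ca[:, j] + F2 @ cb[:, j]) * b
        pm = PotentialMap(U=U, spec=spec, frequency=1.0, times=times)
        fit = fit_potential(pm, N=N)
        scale = np.abs(U).max()
        for _ in range(20):
            s = (rng.uniform(-3.5e-6, 3.5e-6), rng.uniform(-3.5e-6, 3.5e-6),
                 rng.uniform(-0.5e-6, 1.5e-6))
            t = rng.uniform(0, 1)
            xl, yl, zl = s[0] / dx, s[1] / dy, s[2] / sz
            F1 = np.cos(w * t * np.arange(N + 1))
            F2 = np.sin(w * t * np.arange(N + 1))
            vals = np.array(
                [1, xl, yl, zl, xl * yl, xl * zl, yl * zl, xl * yl * zl, xl**2, yl**2, zl**2]
            )
            expect = (F1 @ ca + F2 @ cb) @ vals
            assert fit.eval_U(t, s) == pytest.approx(expect, abs=1e-9 * scale)

    def test_force_matches_finite_differences(self, rng):
        spec = make_spec(nx=11, ny=11)
        x, y, z = spec.node_coords()
        Z, Y, X = np.meshgrid(z, y, x, indexing="ij")
        # smooth non-polynomial landscape
        U0 = 1e-18 * np.sin(X / 2e-6) * np.cos(Y / 3e-6) * np.exp(-Z / 4e-6)
        pm = PotentialMap(U=U0[None], spec=spec, frequency=1.0, times=np.array([0.0]))
        fit = fit_potential(pm, N=0)
        h = spec.spacing[0] / 100
        worst = 0.0
        for _ in range(100):
            s = np.array([rng.uniform(-3e-6, 3e-6), rng.uniform(-3e-6, 3e-6),
                          rng.uniform(-0.3e-6, 1.3e-6)])
            centre = fit.nearest_node(s)
            F = fit.eval_force(0.0, s, centre=centre)
            for ax in range(3):
                dp = np.zeros(3)
                dp[ax] = h
                fd = -(fit.eval_U(0.0, s + dp, centre=centre)
                       - fit.eval_U(0.0, s - dp, centre=centre)) / (2 * h)
                if abs(F[ax]) > 1e-30:
                    worst = max(worst, abs(fd - F[ax]) / max(abs(F[ax]), 1e-30))
        assert worst < 1e-6

    def test_periodic_wrap_is_exact(self, rng):
        spec = make_spec(periodic=(True, False))
        pm = quadratic_map(spec, f=lambda X, Y, Z: np.cos(X / 2) + Y**2)
        fit = fit_potential(pm, N=1)
        L = spec.lengths[0]
        s = (1.1e-6, -2e-6, 0.3e-6)
        assert fit.eval_U(0.3, (s[0] + L, s[1], s[2])) == pytest.approx(
            fit.eval_U(0.3, s), rel=1e-12
        )

    def test_outside_extent_raises_on_nonperiodic_axis(self):
        spec = make_spec()
        pm = quadratic_map(spec)
        fit = fit_potential(pm, N=1)
        with pytest.raises(DomainError):
            fit.eval_U(0.0, (6e-6, 0.0, 0.0))

    def test_adjacent_submatrix_values_agree_within_residuals(self):
        spec = make_spec(nx=11, ny=11)
        x, y, z = spec.node_coords()
        Z, Y, X = np.meshgrid(z, y, x, indexing="ij")
        U0 = 1e-18 * np.exp(-((X**2 + Y**2) / (2 * (3e-6) ** 2))) * (1 + Z / 5e-6)
        pm = PotentialMap(U=U0[None], spec=spec, frequency=1.0, times=np.array([0.0]))
        fit = fit_potential(pm, N=0)
        dx = spec.spacing[0]
        # boundary midway between nodes 4 and 5 along x
        xb = x[4] + dx / 2
        for iy in (3, 5, 7):
            s = (xb, y[iy], 0.5e-6)
            left = fit.eval_U(0.0, s, centre=(1, iy, 4))
            right = fit.eval_U(0.0, s, centre=(1, iy, 5))
            rmax = max(fit.residuals[(1, iy, 4)], fit.residuals[(1, iy, 5)])
            assert abs(left - right) <= 2 * rmax

    def test_hysteretic_node_selection(self):
        spec = make_spec()
        pm = quadratic_map(spec)
        fit = fit_potential(pm, N=1)
        dx = spec.spacing[0]
        x, y, z = spec.node_coords()
        centre = fit.nearest_node((x[4], y[4], 0.0))
        # slightly past the midpoint, but within the hysteresis band: stays
        s_mid = (x[4] + dx / 2, y[4], 0.0)
        assert fit.nearest_node(s_mid, prev=centre)[2] == 4
        # clearly past: hops
        s_far = (x[4] + 0.8 * dx, y[4], 0.0)
        assert fit.nearest_node(s_far, prev=centre)[2] == 5

    def test_submatrix_5_supported(self):
        spec = make_spec(nx=11, ny=11, z=(-1e-6, 0, 1e-6, 2e-6, 3e-6))
        pm = quadratic_map(spec)
        fit = fit_potential(pm, N=1, submatrix=5)
        s = (0.5e-6, -0.5e-6, 0.5e-6)
        f3 = fit_potential(pm, N=1, submatrix=3)
        assert fit.eval_U(0.1, s) == pytest.approx(f3.eval_U(0.1, s), rel=1e-9)

    def test_quasi_2d_single_layer_map(self):
        spec = PotentialGridSpec(
            x_range=(-4e-6, 4e-6), y_range=(-4e-6, 4e-6), n_nodes=(9, 9),
            z_layers=np.array([0.0]),
        )
        x, y, _ = spec.node_coords()
        dx, dy = spec.spacing
        Y, X = np.meshgrid(y / dy, x / dx, indexing="ij")
        U = (X**2 + 2 * Y**2)[None, None] * 1e-18
        pm = PotentialMap(U=U, spec=spec, frequency=1.0, times=np.array([0.0]))
        fit = fit_potential(pm, N=0)
        F = fit.eval_force(0.0, (1e-6, 1e-6, 0.0))
        assert F[2] == 0.0
        np.testing.assert_allclose(
            F[:2], [-2 * (1e-6 / dx) / dx * 1e-18, -4 * (1e-6 / dy) / dy * 1e-18], rtol=1e-9
        )
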