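"""Landscape, flux and metrics: analytic toys plus circuit checks."""

import numpy as np
import pytest

import bgflux as bg
from bgflux.landscape import (
    FluxField,
    LandscapeGrid,
    average_flux,
    barrier_height,
    decomposition_residual,
    entropy_production_rate,
    flux_field,
    potential_from_probability,
)
from bgflux.moments import GridSpec, ProbabilityGrid

from conftest import unit_circle_cycle


def make_probability(grid, values, projection=("cortex", "thalamus")):
    P = ProbabilityGrid(projection, grid, values)
    return P.normalized()


def isotropic_gaussian(grid, sigma, mu=(0.0, 0.0)):
    X, Y = np.meshgrid(grid.x_centers, grid.y_centers, indexing="ij")
    g = np.exp(-((X - mu[0]) ** 2 + (Y - mu[1]) ** 2) / (2 * sigma))
    return make_probability(grid, g), (X, Y)


class TestPotential:
    def test_uniform_probability_gives_flat_potential(self):
        grid = GridSpec((0, 1), (0, 1), 20, 20)
        P = make_probability(grid, np.ones((20, 20)))
        U = potential_from_probability(P)
        assert np.ptp(U.U) == pytest.approx(0.0, abs=1e-12)

    def test_two_level_log_ratio(self):
        grid = GridSpec((0, 2), (0, 1), 2, 2)
        lo, hi = np.exp(-1.0), 1 - np.exp(-1.0)
        vals = np.array([[lo, lo], [hi, hi]])
        U = potential_from_probability(make_probability(grid, vals))
        assert U.U[0, 0] - U.U[1, 0] == pytest.approx(np.log(hi / lo))

    def test_gaussian_curvature_recovered_by_quadratic_fit(self):
        # U of a Gaussian is x^2/(2 sigma) + const per axis
        sigma = 0.5
        grid = GridSpec((-2, 2), (-2, 2), 201, 201)
        P, _ = isotropic_gaussian(grid, sigma)
        U = potential_from_probability(P)
        x = grid.x_centers
        mid = U.U[:, 100]
        coeff = np.polyfit(x, mid, 2)
        assert coeff[0] == pytest.approx(1.0 / (2 * sigma), rel=1e-2)

    def test_argmin_matches_argmax(self, oscillatory_landscape):
        P, U, _, _ = oscillatory_landscape
        assert np.argmin(U.U) == np.argmax(P.P)

    def test_unnormalised_input_rejected(self):
        grid = GridSpec((0, 1), (0, 1), 10, 10)
        P = ProbabilityGrid(("cortex", "thalamus"), grid,
                            np.full((10, 10), 3.0))
        with pytest.raises(ValueError, match="normalis"):
            potential_from_probability(P)


class TestFluxField:
    def test_equilibrium_ou_flux_vanishes(self):
        # gradient drift with matched Gaussian: detailed balance, J = 0
        D, k = 0.002, 0.002  # sigma = D/k = 1
        grid = GridSpec((-2, 2), (-2, 2), 400, 400)
        P, (X, Y) = isotropic_gaussian(grid, D / k)
        J = flux_field(P, (-k * X, -k * Y), D)
        assert np.abs(J.magnitude).max() < 1e-6

    def test_floor_cells_carry_zero_flux(self):
        grid = GridSpec((-8, 8), (-8, 8), 100, 100)
        P, (X, Y) = isotropic_gaussian(grid, 0.05)
        J = flux_field(P, (np.ones_like(X), np.ones_like(X)), 0.01)
        assert J.at_floor.any()
        assert np.all(J.magnitude[J.at_floor] == 0.0)

    def test_hopf_toy_flux_is_tangential(self):
        # rotational drift with ring-Gaussian stationary density: the
        # radial flux component must be negligible on the ring
        D, omega, mu = 0.01, 0.5, 2.0
        sr = D / mu  # radial variance of the ring Gaussian
        grid = GridSpec((-1.6, 1.6), (-1.6, 1.6), 400, 400)
        X, Y = np.meshgrid(grid.x_centers, grid.y_centers, indexing="ij")
        R = np.hypot(X, Y)
        P = make_probability(grid, np.exp(-((R - 1.0) ** 2) / (2 * sr)))
        # drift: radial relaxation to r=1 plus rotation
        with np.errstate(invalid="ignore", divide="ignore"):
            ex, ey = X / np.maximum(R, 1e-12), Y / np.maximum(R, 1e-12)
        Fx = -mu * (R - 1.0) * ex - omega * Y
        Fy = -mu * (R - 1.0) * ey + omega * X
        J = flux_field(P, (Fx, Fy), D)
        ring = np.abs(R - 1.0) < 0.02
        radial = np.abs(J.Jx * ex + J.Jy * ey)[ring]
        tangential = np.abs(-J.Jx * ey + J.Jy * ex)[ring]
        assert radial.max() < 0.01 * tangential.max()

    def test_grid_mismatch_rejected(self, oscillatory_landscape):
        P = oscillatory_landscape[0]
        with pytest.raises(ValueError):
            flux_field(P, (np.ones((3, 3)), np.ones((3, 3))), 0.01)


class TestDecompositionResidual:
    def test_analytic_ou_residual_tiny(self):
        D, k = 0.002, 0.002
        grid = GridSpec((-2, 2), (-2, 2), 400, 400)
        P, (X, Y) = isotropic_gaussian(grid, D / k)
        F = (-k * X, -k * Y)
        U = potential_from_probability(P)
        J = flux_field(P, F, D)
        res, _ = decomposition_residual(F, J, U, P, D)
        assert np.nanmax(res) < 1e-6

    def test_divergence_free_in_analytic_steady_state(self):
        # same OU configuration: div J -> 0 under refinement
        D, k = 0.02, 0.5
        sigma = D / k
        maxdiv = []
        for n in (100, 200):
            grid = GridSpec((-1, 1), (-1, 1), n, n)
            P, (X, Y) = isotropic_gaussian(grid, sigma)
            J = flux_field(P, (-k * X, -k * Y), D)
            div = (np.gradient(J.Jx, grid.dx, axis=0)
                   + np.gradient(J.Jy, grid.dy, axis=1))
            mask = P.P > 1e-3 * P.P.max()
            maxdiv.append(np.abs(div[mask]).max())
        assert maxdiv[1] < maxdiv[0]

    def test_floor_cells_reported_not_counted(self, oscillatory_landscape):
        P, U, J, _ = oscillatory_landscape
        res, n_excluded = decomposition_residual(J.drift2d, J, U, P, 0.01)
        assert n_excluded > 0
        assert np.isnan(res).sum() == n_excluded


class TestBarrier:
    def test_mexican_hat_barrier_is_exactly_one(self):
        # U(r) = (r^2 - 1)^2: zero on the unit ring, one at the centre
        grid = GridSpec((-1.5, 1.5), (-1.5, 1.5), 301, 301)
        X, Y = np.meshgrid(grid.x_centers, grid.y_centers, indexing="ij")
        U = LandscapeGrid(("cortex", "thalamus"), grid,
                          (X**2 + Y**2 - 1.0) ** 2, floor=0.0)
        cycle = unit_circle_cycle(n=4000)
        U_max, U_min, barrier, max_loc, _ = barrier_height(U, cycle)
        assert U_min == pytest.approx(0.0, abs=1e-4)
        assert U_max == pytest.approx(1.0, abs=1e-4)
        assert barrier == pytest.approx(1.0, abs=2e-4)
        assert np.hypot(*max_loc) < 2 * grid.dx  # hump at the origin

    def test_flat_potential_has_zero_barrier(self):
        grid = GridSpec((-1.5, 1.5), (-1.5, 1.5), 100, 100)
        U = LandscapeGrid(("cortex", "thalamus"), grid,
                          np.full((100, 100), 2.2), floor=0.0)
        _, _, barrier, _, _ = barrier_height(U, unit_circle_cycle())
        assert barrier == pytest.approx(0.0, abs=1e-12)

    def test_missing_cycle_raises(self, monostable_landscape):
        _, U, _, _ = monostable_landscape
        with pytest.raises(ValueError, match="mono-stable"):
            barrier_height(U, None)


class TestAverageFlux:
    def test_zero_flux_integrates_to_zero(self):
        grid = GridSpec((-1.5, 1.5), (-1.5, 1.5), 100, 100)
        Z = np.zeros((100, 100))
        J = FluxField(("cortex", "thalamus"), grid, Z, Z)
        assert average_flux(J, unit_circle_cycle()) == 0.0

    def test_constant_tangential_magnitude_recovered(self):
        c = 0.37
        grid = GridSpec((-1.5, 1.5), (-1.5, 1.5), 400, 400)
        X, Y = np.meshgrid(grid.x_centers, grid.y_centers, indexing="ij")
        R = np.maximum(np.hypot(X, Y), 1e-12)
        J = FluxField(("cortex", "thalamus"), grid,
                      -c * Y / R, c * X / R)
        assert average_flux(J, unit_circle_cycle()) == pytest.approx(
            c, rel=1e-3)

    def test_resampling_stability(self, oscillatory_landscape):
        P, _, J, _ = oscillatory_landscape
        j1 = average_flux(J, P.cycle, n_points=2000)
        j2 = average_flux(J, P.cycle, n_points=8000)
        assert j1 == pytest.approx(j2, rel=5e-3)


class TestEntropyProduction:
    def test_equilibrium_is_dissipation_free(self):
        D, k = 0.002, 0.002
        grid = GridSpec((-2, 2), (-2, 2), 200, 200)
        P, (X, Y) = isotropic_gaussian(grid, D / k)
        J = flux_field(P, (-k * X, -k * Y), D)
        assert entropy_production_rate(P, J, D) < 1e-10

    def test_quadratic_in_flux(self, oscillatory_landscape):
        P, _, J, _ = oscillatory_landscape
        e1 = entropy_production_rate(P, J, 0.01)
        J2 = FluxField(P.projection, P.grid, 2 * J.Jx, 2 * J.Jy)
        assert entropy_production_rate(P, J2, 0.01) == pytest.approx(
            4 * e1, rel=1e-12)
        assert e1 >= 0

    def test_zero_diffusion_rejected(self, oscillatory_landscape):
        P, _, J, _ = oscillatory_landscape
        with pytest.raises(ValueError):
            entropy_production_rate(P, J, 0.0)


class TestCircuitFluxStructure:
    def test_flux_parallel_to_cycle_on_ring(self, oscillatory_landscape):
        from bgflux.landscape import _interp, _resample_closed

        P, _, J, _ = oscillatory_landscape
        ring = _resample_closed(P.cycle.projected(P.projection), 2000)
        jx = _interp(J.grid, J.Jx)(ring)
        jy = _interp(J.grid, J.Jy)(ring)
        seg = np.diff(ring, axis=0)
        ds = np.hypot(seg[:, 0], seg[:, 1])
        tx, ty = seg[:, 0] / ds, seg[:, 1] / ds
        jmx, jmy = 0.5 * (jx[:-1] + jx[1:]), 0.5 * (jy[:-1] + jy[1:])
        jm = np.maximum(np.hypot(jmx, jmy), 1e-300)
        cosang = (jmx * tx + jmy * ty) / jm
        angles = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
        assert np.median(angles) < 15.0

    def test_flux_velocity_relation(self, oscillatory_params,
                                    oscillatory_landscape):
        # |J|/P along the ring correlates with the deterministic speed
        from bgflux.landscape import _interp

        P, _, J, _ = oscillatory_landscape
        pts = P.cycle.y[::25]
        proj = pts[:, [0, 5]]
        speeds = np.array([np.hypot(*bg.drift(x, oscillatory_params)[[0, 5]])
                           for x in pts])
        v_flux = (np.hypot(_interp(J.grid, J.Jx)(proj),
                           _interp(J.grid, J.Jy)(proj))
                  / np.maximum(_interp(P.grid, P.P)(proj), 1e-300))
        r = np.corrcoef(v_flux, speeds)[0, 1]
        assert r > 0.8
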