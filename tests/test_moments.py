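"""Moment closure: derivatives, evolution, Gaussian projection grids."""

import numpy as np
import pytest

import bgflux as bg
from bgflux.moments import ClosureBreakdownError, GridSpec


class TestMomentDerivatives:
    def test_leak_only_variance_relaxation(self, leak_only_params):
        p = leak_only_params.with_(D_diff=0.01)
        m = bg.MomentState(np.ones(7), np.full(7, 0.02))
        du, ds = bg.moment_derivatives(m, p)
        np.testing.assert_allclose(ds, -(2 / 6.0) * 0.02 + 2 * 0.01)
        # stationary variance D * tau
        m_stat = bg.MomentState(np.ones(7), np.full(7, 0.01 * 6.0))
        _, ds_stat = bg.moment_derivatives(m_stat, p)
        np.testing.assert_allclose(ds_stat, 0.0, atol=1e-15)

    def test_noiseless_zero_variance_is_invariant(self, default_params):
        p = default_params.with_(D_diff=0.0)
        m = bg.MomentState(np.ones(7), np.zeros(7))
        _, ds = bg.moment_derivatives(m, p)
        np.testing.assert_array_equal(ds, np.zeros(7))

    def test_mean_equation_is_the_drift(self, oscillatory_params):
        m = bg.MomentState(np.full(7, 1.3), np.full(7, 0.05))
        du, _ = bg.moment_derivatives(m, oscillatory_params)
        np.testing.assert_array_equal(du, bg.drift(m.u, oscillatory_params))

    def test_against_euler_propagation_oracle(self):
        """Independent fixed-step propagation of the same closed system
        over 1 ms reproduces the adaptive integration to 1e-6."""
        p = bg.CircuitParameters(D_input=1.2)

        def rhs(z):
            A = bg.jacobian(z[:7], p)
            return np.concatenate([
                bg.drift(z[:7], p),
                2 * np.diag(A) * z[7:] + 2 * p.D_diff])

        z = np.concatenate([np.full(7, 1.1), np.full(7, 0.03)])
        dt = 1e-3
        for _ in range(1000):  # classical RK4, fixed step
            k1 = rhs(z)
            k2 = rhs(z + dt / 2 * k1)
            k3 = rhs(z + dt / 2 * k2)
            k4 = rhs(z + dt * k3)
            z = z + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        u, sig = z[:7], z[7:]
        states = bg.evolve_moments(bg.MomentState(np.full(7, 1.1),
                                                  np.full(7, 0.03)),
                                   p, 1.0, t_eval=[1.0])
        np.testing.assert_allclose(states[-1].u, u, atol=1e-6)
        np.testing.assert_allclose(states[-1].sigma, sig, atol=1e-6)


class TestEvolveMoments:
    def test_leak_only_variance_closed_form(self, leak_only_params):
        p = leak_only_params.with_(D_diff=0.01)
        ts = np.linspace(0.5, 30.0, 10)
        states = bg.evolve_moments(
            bg.MomentState(np.zeros(7), np.zeros(7)), p, 30.0, t_eval=ts)
        for m in states:
            expected = 0.01 * 6.0 * (1 - np.exp(-2 * m.time / 6.0))
            np.testing.assert_allclose(m.sigma, expected, rtol=1e-6,
                                       atol=1e-9)

    def test_stationary_start_stays_constant(self, leak_only_params):
        p = leak_only_params.with_(D_diff=0.01)
        u0 = np.array(p.I) * p.R
        s0 = np.full(7, 0.06)
        states = bg.evolve_moments(bg.MomentState(u0, s0), p, 100.0,
                                   t_eval=[50.0, 100.0])
        for m in states:
            np.testing.assert_allclose(m.u, u0, atol=1e-8)
            np.testing.assert_allclose(m.sigma, s0, atol=1e-8)

    def test_mean_follows_deterministic_cycle(self, oscillatory_params,
                                              oscillatory_cycle):
        m0 = bg.MomentState(oscillatory_cycle.y[0], np.full(7, 0.06))
        ts = oscillatory_cycle.t
        states = bg.evolve_moments(m0, oscillatory_params, float(ts[-1]),
                                   t_eval=ts)
        u_mean = np.trapezoid([m.u for m in states], ts, axis=0) / ts[-1]
        y_mean = np.trapezoid(oscillatory_cycle.y, ts, axis=0) / ts[-1]
        np.testing.assert_allclose(u_mean, y_mean, atol=1e-6)

    def test_negative_variance_state_rejected(self):
        with pytest.raises(ClosureBreakdownError):
            bg.MomentState(np.ones(7), np.array([0.1] * 6 + [-0.01]))


class TestGaussianProjection:
    def test_standard_normal_product(self):
        m = bg.MomentState(np.zeros(7), np.ones(7))
        grid = GridSpec((-6, 6), (-6, 6), 121, 121)
        P = bg.gaussian_probability_2d(m, grid, ("cortex", "thalamus"))
        assert abs(P.mass - 1.0) < 1e-8
        i, j = np.unravel_index(np.argmax(P.P), P.P.shape)
        assert abs(grid.x_centers[i]) < grid.dx
        assert abs(grid.y_centers[j]) < grid.dy

    def test_peak_height_is_product_of_normalisation_constants(self):
        sigma = 0.06
        m = bg.MomentState(np.zeros(7), np.full(7, sigma))
        grid = GridSpec((-2, 2), (-2, 2), 401, 401)  # odd: cell centred at 0
        P = bg.gaussian_probability_2d(m, grid, ("cortex", "thalamus"))
        # 1-D peak height 1/sqrt(2 pi sigma) = 1.629 for sigma = 0.06
        assert 1.0 / np.sqrt(2 * np.pi * sigma) == pytest.approx(1.629,
                                                                 abs=1e-3)
        assert P.P.max() == pytest.approx(1.629**2, rel=1e-3)

    def test_truncating_grid_still_normalised(self):
        m = bg.MomentState(np.zeros(7), np.ones(7))
        grid = GridSpec((-0.5, 0.5), (-0.5, 0.5), 51, 51)
        P = bg.gaussian_probability_2d(m, grid, ("cortex", "thalamus"))
        assert abs(P.mass - 1.0) < 1e-8

    def test_zero_variance_raises(self):
        m = bg.MomentState(np.zeros(7), np.zeros(7))
        grid = GridSpec((-1, 1), (-1, 1), 11, 11)
        with pytest.raises(ValueError, match="variance"):
            bg.gaussian_probability_2d(m, grid, ("cortex", "thalamus"))


class TestSteadyStateProbability:
    def test_leak_only_centred_at_input_times_resistance(self,
                                                         leak_only_params):
        p = leak_only_params.with_(D_diff=0.01)
        P = bg.steady_state_probability(p, projection=("cortex", "thalamus"),
                                        nx=101, ny=101)
        i, j = np.unravel_index(np.argmax(P.P), P.P.shape)
        assert P.grid.x_centers[i] == pytest.approx(p.I[0] * p.R,
                                                    abs=P.grid.dx)
        assert P.grid.y_centers[j] == pytest.approx(p.I[5] * p.R,
                                                    abs=P.grid.dy)

    def test_period_average_of_constant_moments_is_snapshot(self):
        # averaging identical snapshots must return the snapshot
        m = bg.MomentState(np.ones(7), np.full(7, 0.06))
        grid = GridSpec((0, 2), (0, 2), 80, 80)
        snap = bg.gaussian_probability_2d(m, grid, ("cortex", "thalamus"))
        avg = np.mean([bg.gaussian_probability_2d(m, grid,
                                                  ("cortex", "thalamus")).P
                       for _ in range(10)], axis=0)
        np.testing.assert_allclose(avg, snap.P, rtol=1e-12)

    def test_probability_ridge_tracks_deterministic_cycle(
            self, oscillatory_params, oscillatory_cycle,
            oscillatory_landscape):
        P, U, J, _ = oscillatory_landscape
        # the crest of the period-averaged density lies on the cycle's
        # Gaussian tube (within one closure standard deviation); the
        # global maximum shifts toward the concave side of the slow
        # segment because nearby phases overlap there
        proj = oscillatory_cycle.projected(("cortex", "thalamus"))
        i, j = np.unravel_index(np.argmax(P.P), P.P.shape)
        crest = np.array([P.grid.x_centers[i], P.grid.y_centers[j]])
        d = np.min(np.hypot(proj[:, 0] - crest[0], proj[:, 1] - crest[1]))
        tube_sigma = np.sqrt(0.01 * 6.0)  # D_diff * tau
        assert d <= tube_sigma
        # and the deepest point of the ring valley is a low-potential
        # cell: every cycle point has U below the interior hump
        from bgflux.landscape import _interp, _resample_closed
        ring = _resample_closed(proj, 2000)
        u_ring = _interp(U.grid, U.U)(ring)
        assert u_ring.min() < U.U.max() - 1.0

    def test_snapshot_count_convergence(self, oscillatory_params):
        # doubling the phase count barely changes the period average
        P200 = bg.steady_state_probability(oscillatory_params, nx=100,
                                           ny=100, n_snapshots=200)
        P400 = bg.steady_state_probability(
            oscillatory_params, grid=P200.grid, n_snapshots=400)
        tv = 0.5 * np.abs(P200.P - P400.P).sum() * P200.grid.cell_area
        assert tv < 1e-4

    def test_all_grids_normalised(self, oscillatory_landscape,
                                  monostable_landscape):
        for bundle in (oscillatory_landscape, monostable_landscape):
            assert abs(bundle[0].mass - 1.0) < 1e-8
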