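"""Gaussian moment closure and steady-state probability grids.

The stochastic circuit is reduced to coupled equations for the mean
vector u(t) and the diagonal variances sigma(t):

    du/dt     = F(u)
    dsigma/dt = diag(sigma A^T + A sigma + 2 D),

with A the drift Jacobian evaluated at the mean and D the scalar
diffusion coefficient applied to every coordinate.  Because the
off-diagonal covariances are dropped (mean-field product ansatz) the
diagonal equation reduces to dsigma_ii/dt = 2 A_ii sigma_ii + 2 D.

The joint probability is factorised into per-variable Gaussian
marginals; a 2-D projection of the steady state is then either the
converged snapshot (mono-stable regime) or the uniform-in-time average
of snapshots over exactly one period of the converged oscillatory
moment orbit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .circuit import drift, jacobian
from .dynamics import (
    IntegrationError,
    LimitCycle,
    detect_limit_cycle,
    resolve_projection,
    track_fixed_point,
)
from .params import MODULE_NAMES, CircuitParameters, StimulationProtocol

__all__ = [
    "MomentState",
    "GridSpec",
    "ProbabilityGrid",
    "ClosureBreakdownError",
    "moment_derivatives",
    "evolve_moments",
    "gaussian_probability_2d",
    "steady_state_probability",
]

VARIANCE_FLOOR = 1e-8  # applied before logs downstream


class ClosureBreakdownError(RuntimeError):
    """A diagonal variance went negative: the Gaussian closure failed."""

    def __init__(self, message, time=None, component=None):
        super().__init__(message)
        self.time = time
        self.component = component


@dataclass
class MomentState:
    """Mean vector and diagonal variances of the Gaussian closure."""

    u: np.ndarray
    sigma: np.ndarray
    time: float = 0.0

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.u.shape != (7,) or self.sigma.shape != (7,):
            raise ValueError("moment state requires length-7 u and sigma")
        if np.any(self.sigma < 0):
            i = int(np.argmin(self.sigma))
            raise ClosureBreakdownError(
                f"negative variance sigma[{i}] = {self.sigma[i]:.3e}",
                time=self.time, component=i)


@dataclass(frozen=True)
class GridSpec:
    """Cell-centred rectangular grid for 2-D projections."""

    x_range: tuple
    y_range: tuple
    nx: int = 200
    ny: int = 200

    def __post_init__(self):
        if self.nx < 2 or self.ny < 2:
            raise ValueError("grid needs at least 2 cells per axis")
        if self.x_range[1] <= self.x_range[0] or self.y_range[1] <= self.y_range[0]:
            raise ValueError("grid ranges must be increasing")

    @property
    def dx(self) -> float:
        return (self.x_range[1] - self.x_range[0]) / self.nx

    @property
    def dy(self) -> float:
        return (self.y_range[1] - self.y_range[0]) / self.ny

    @property
    def cell_area(self) -> float:
        return self.dx * self.dy

    @property
    def x_centers(self) -> np.ndarray:
        return self.x_range[0] + self.dx * (np.arange(self.nx) + 0.5)

    @property
    def y_centers(self) -> np.ndarray:
        return self.y_range[0] + self.dy * (np.arange(self.ny) + 0.5)

    def refined(self, factor: int = 2) -> "GridSpec":
        return GridSpec(self.x_range, self.y_range,
                        self.nx * factor, self.ny * factor)

    @staticmethod
    def around(points: np.ndarray, sigma_max: float,
               nx: int = 200, ny: int = 200, pad_sigmas: float = 4.0) -> "GridSpec":
        """Auto range: attractor projection padded by 4 sqrt(sigma_max)."""
        pad = pad_sigmas * np.sqrt(max(sigma_max, VARIANCE_FLOOR))
        lo = points.min(axis=0) - pad
        hi = points.max(axis=0) + pad
        return GridSpec((float(lo[0]), float(hi[0])),
                        (float(lo[1]), float(hi[1])), nx, ny)


@dataclass
class ProbabilityGrid:
    """Normalised steady-state probability on a 2-D projection grid.

    ``P[i, j]`` is the probability density at ``(x_centers[i],
    y_centers[j])``; ``sum(P) * cell_area == 1``.
    """

    projection: tuple
    grid: GridSpec
    P: np.ndarray
    #: per-phase snapshot moments (oscillatory regime), for drift closure
    phases: list = field(default=None, repr=False)
    period: float = None
    cycle: LimitCycle = field(default=None, repr=False)
    fixed_point: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self.P = np.asarray(self.P, dtype=float)
        if self.P.shape != (self.grid.nx, self.grid.ny):
            raise ValueError("P shape does not match grid")
        if np.any(self.P < 0):
            raise ValueError("probabilities must be nonnegative")

    @property
    def mass(self) -> float:
        return float(self.P.sum() * self.grid.cell_area)

    def normalized(self) -> "ProbabilityGrid":
        out = ProbabilityGrid(self.projection, self.grid, self.P / self.mass,
                              phases=self.phases, period=self.period,
                              cycle=self.cycle, fixed_point=self.fixed_point)
        return out


def moment_derivatives(m: MomentState, params: CircuitParameters,
                       protocol: StimulationProtocol | None = None):
    """Right-hand side (du/dt, dsigma/dt) of the closed moment equations."""
    du = drift(m.u, params, protocol)
    A = jacobian(m.u, params, protocol)
    dsigma = 2.0 * np.diag(A) * m.sigma + 2.0 * params.D_diff
    return du, dsigma


def evolve_moments(m0: MomentState, params: CircuitParameters,
                   duration: float,
                   protocol: StimulationProtocol | None = None,
                   t_eval=None, rtol: float = 1e-7, atol: float = 1e-9,
                   dense_output: bool = False):
    """Integrate the closed moment equations for ``duration`` ms.

    Returns a list of :class:`MomentState`; with ``dense_output=True``
    returns ``(states, interpolant)``.  A variance dipping below
    -1e-12 terminates integration with :class:`ClosureBreakdownError`.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")

    def rhs(t, z):
        m = MomentState(z[:7], np.maximum(z[7:], 0.0), time=t)
        du, ds = moment_derivatives(m, params, protocol)
        return np.concatenate([du, ds])

    def breakdown(t, z):
        return float(z[7:].min() + 1e-12)

    breakdown.terminal = True
    breakdown.direction = -1

    z0 = np.concatenate([np.asarray(m0.u, float), np.asarray(m0.sigma, float)])
    sol = solve_ivp(rhs, (0.0, duration), z0, rtol=rtol, atol=atol,
                    t_eval=t_eval, dense_output=dense_output,
                    events=breakdown, method="RK45")
    if sol.t_events[0].size:
        t_bad = float(sol.t_events[0][0])
        z_bad = sol.y_events[0][0]
        i = int(np.argmin(z_bad[7:]))
        raise ClosureBreakdownError(
            f"variance sigma[{i}] crossed zero at t = {t_bad:.3f} ms",
            time=t_bad, component=i)
    if not sol.success:
        raise IntegrationError(sol.message, t=sol.t[-1], x=sol.y[:, -1])
    states = [MomentState(sol.y[:7, k], np.maximum(sol.y[7:, k], 0.0),
                          time=float(sol.t[k]))
              for k in range(sol.t.size)]
    if dense_output:
        return states, sol.sol
    return states


def gaussian_probability_2d(m: MomentState, grid: GridSpec,
                            projection) -> ProbabilityGrid:
    """Product of the two projected Gaussian marginals on the grid.

    The mean-field ansatz factorises the 7-D probability into
    independent marginals, so the 2-D projection is exactly
    N(x_a; u_a, sigma_a) * N(x_b; u_b, sigma_b), evaluated at cell
    centres and renormalised on the grid.
    """
    a, b = resolve_projection(projection)
    sa, sb = m.sigma[a], m.sigma[b]
    if sa <= 0 or sb <= 0:
        raise ValueError(
            "zero variance on a projected component; apply a variance "
            f"floor (e.g. {VARIANCE_FLOOR}) before building grids")
    ga = np.exp(-((grid.x_centers - m.u[a]) ** 2) / (2 * sa)) / np.sqrt(2 * np.pi * sa)
    gb = np.exp(-((grid.y_centers - m.u[b]) ** 2) / (2 * sb)) / np.sqrt(2 * np.pi * sb)
    P = np.outer(ga, gb)
    return ProbabilityGrid(tuple(projection), grid, P).normalized()


def _converged_moments(params, protocol, fp, rtol=1e-9):
    """Converged moments in the mono-stable regime.

    With no self-coupling the diagonal Jacobian is the pure leak
    -1/tau, so the stationary variance is D_diff * tau on every
    coordinate; the mean sits at the fixed point.  Computed by
    relaxation for generality, seeded at the analytic values.
    """
    m0 = MomentState(fp, np.full(7, params.D_diff * params.tau))
    states = evolve_moments(m0, params, 20.0 * params.tau, protocol,
                            t_eval=[20.0 * params.tau])
    return states[-1]


def steady_state_probability(params: CircuitParameters,
                             protocol: StimulationProtocol | None = None,
                             projection=("cortex", "thalamus"),
                             grid: GridSpec | None = None,
                             n_snapshots: int = 200,
                             nx: int = 200, ny: int = 200) -> ProbabilityGrid:
    """Steady-state probability of the projection under the closure.

    Mono-stable regime: the converged-moment snapshot.  Oscillatory
    regime: the average of ``n_snapshots`` snapshots uniformly phased
    over exactly one period of the converged moment orbit,
    renormalised.  The regime is classified from the deterministic
    dynamics (fixed-point stability plus limit-cycle detection).
    """
    a, b = resolve_projection(projection)
    fp = track_fixed_point(params, protocol)
    cycle = None
    if fp is not None and fp.leading_real_part > 0:
        lam = max(fp.leading_real_part, 1e-4)
        cycle = detect_limit_cycle(
            params, protocol, transient=min(max(3000.0, 10.0 / lam), 4e4))
    if fp is None and cycle is None:
        raise RuntimeError("dynamics neither converged nor periodic: "
                           "cannot classify the steady state")

    sigma_stat = np.full(7, max(params.D_diff * params.tau, VARIANCE_FLOOR))

    if cycle is None:
        m = _converged_moments(params, protocol, fp.location)
        m.sigma = np.maximum(m.sigma, VARIANCE_FLOOR)
        if grid is None:
            pt = fp.location[[a, b]][None, :]
            grid = GridSpec.around(pt, float(m.sigma[[a, b]].max()), nx, ny)
        out = gaussian_probability_2d(m, grid, projection)
        out.phases = [m]
        out.fixed_point = fp.location
        return out

    # oscillatory: converge the moment orbit onto the cycle, then sample
    # one period uniformly in time
    m0 = MomentState(cycle.y[0], sigma_stat)
    settle = 5.0 * cycle.period
    states = evolve_moments(m0, params, settle, protocol, t_eval=[settle])
    m1 = states[-1]
    phases_t = np.linspace(0.0, cycle.period, n_snapshots, endpoint=False)
    phase_states = evolve_moments(
        MomentState(m1.u, np.maximum(m1.sigma, VARIANCE_FLOOR)),
        params, cycle.period, protocol, t_eval=phases_t)
    if grid is None:
        smax = float(max(s.sigma[[a, b]].max() for s in phase_states))
        grid = GridSpec.around(cycle.projected(projection), smax, nx, ny)
    P = np.zeros((grid.nx, grid.ny))
    for m in phase_states:
        m.sigma = np.maximum(m.sigma, VARIANCE_FLOOR)
        P += gaussian_probability_2d(m, grid, projection).P
    P /= n_snapshots
    out = ProbabilityGrid(tuple(projection), grid, P,
                          phases=phase_states, period=cycle.period,
                          cycle=cycle).normalized()
    return out
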