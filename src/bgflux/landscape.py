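"""Potential landscape, curl flux, and non-equilibrium stability metrics.

The steady-state probability P_ss on a 2-D projection defines the
potential U = -ln P_ss.  The probability flux

    J = F P - D grad(P)

is nonzero in a non-equilibrium steady state and decomposes the drift
as F = J_ss/P_ss - D grad(U): a gradient (downhill) force plus a
divergence-free curl flux that drives rotation along the oscillation
ring.  Scalar summaries:

* barrier height  U_max (interior local maximum) - U_min (on the ring),
* average flux    J_Average = loop integral of |J| dl / loop length,
* entropy production rate  sum over cells of |J|^2 / (D P) * cell area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib.path import Path as MplPath
from scipy.interpolate import RegularGridInterpolator

from .circuit import drift
from .dynamics import LimitCycle, resolve_projection, track_fixed_point
from .moments import GridSpec, ProbabilityGrid, steady_state_probability
from .params import CircuitParameters, StimulationProtocol

__all__ = [
    "LandscapeGrid",
    "FluxField",
    "LandscapeMetrics",
    "potential_from_probability",
    "drift_2d_on_grid",
    "flux_field",
    "decomposition_residual",
    "barrier_height",
    "average_flux",
    "entropy_production_rate",
    "analyze_condition",
]

PROBABILITY_FLOOR = 1e-12  # relative to the grid maximum, before logs


@dataclass
class LandscapeGrid:
    """Potential U = -ln(max(P, floor)) on a probability grid."""

    projection: tuple
    grid: GridSpec
    U: np.ndarray
    floor: float

    def __post_init__(self):
        self.U = np.asarray(self.U, dtype=float)
        if not np.all(np.isfinite(self.U)):
            raise ValueError("potential must be finite everywhere")


@dataclass
class FluxField:
    """2-component probability flux per cell, plus the drift used."""

    projection: tuple
    grid: GridSpec
    Jx: np.ndarray
    Jy: np.ndarray
    drift2d: tuple = field(default=None, repr=False)
    at_floor: np.ndarray = field(default=None, repr=False)

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.Jx, self.Jy)


@dataclass
class LandscapeMetrics:
    """Scalar summaries of one landscape/flux computation."""

    barrier_height: float
    U_max: float
    U_min: float
    U_max_location: tuple
    U_min_location: tuple
    average_flux: float
    entropy_production_rate: float
    period: float = np.nan
    loop_length: float = np.nan


def potential_from_probability(P: ProbabilityGrid,
                               floor: float = PROBABILITY_FLOOR) -> LandscapeGrid:
    """U = -ln(max(P, floor * P.max())).

    The floor keeps U finite in the far tails; the argmin of U is the
    argmax of P by construction.
    """
    if abs(P.mass - 1.0) > 1e-6:
        raise ValueError(f"probability grid not normalised (mass {P.mass:.6f})")
    abs_floor = floor * float(P.P.max())
    U = -np.log(np.maximum(P.P, abs_floor))
    return LandscapeGrid(P.projection, P.grid, U, floor=abs_floor)


def _phase_weighted_means(P: ProbabilityGrid):
    """Probability-weighted conditional means of the 5 off-projection
    coordinates per grid cell, built from the per-phase snapshots."""
    from .moments import gaussian_probability_2d

    grid = P.grid
    num = np.zeros((grid.nx, grid.ny, 7))
    den = np.zeros((grid.nx, grid.ny))
    for m in P.phases:
        Pk = gaussian_probability_2d(m, grid, P.projection).P
        den += Pk
        num += Pk[:, :, None] * m.u[None, None, :]
    den = np.maximum(den, 1e-300)
    return num / den[:, :, None]


def drift_2d_on_grid(params: CircuitParameters, P: ProbabilityGrid,
                     protocol: StimulationProtocol | None = None,
                     closure: str = "phase_mean"):
    """Evaluate the two projected drift components on every grid cell.

    The drift is a function of all 7 coordinates; on a 2-D grid the
    other 5 must be closed.  ``phase_mean`` (default) sets them to
    their probability-weighted conditional means at the same phase
    (oscillatory) or to the fixed-point values (mono-stable);
    ``nearest_orbit`` uses the full state of the nearest point on the
    deterministic orbit.  Both are documented approximations.
    """
    a, b = resolve_projection(P.projection)
    grid = P.grid
    X, Y = np.meshgrid(grid.x_centers, grid.y_centers, indexing="ij")

    if P.phases is not None and len(P.phases) > 1 and closure == "phase_mean":
        base = _phase_weighted_means(P)
    elif closure == "nearest_orbit" and P.cycle is not None:
        orbit = P.cycle.y
        pts = np.stack([X.ravel(), Y.ravel()], axis=1)
        proj = orbit[:, [a, b]]
        d2 = ((pts[:, None, :] - proj[None, :, :]) ** 2).sum(axis=2)
        nearest = np.argmin(d2, axis=1)
        base = orbit[nearest].reshape(grid.nx, grid.ny, 7)
    else:
        if P.fixed_point is not None:
            ref = P.fixed_point
        elif P.phases:
            ref = P.phases[0].u
        else:
            fp = track_fixed_point(params, protocol)
            ref = fp.location
        base = np.broadcast_to(ref, (grid.nx, grid.ny, 7)).copy()

    states = base.copy()
    states[:, :, a] = X
    states[:, :, b] = Y

    flat = states.reshape(-1, 7)
    Fa = np.empty(flat.shape[0])
    Fb = np.empty(flat.shape[0])
    # vectorise drift over cells in chunks to bound memory
    chunk = 20000
    for k in range(0, flat.shape[0], chunk):
        block = flat[k:k + chunk]
        F = _drift_batch(block, params, protocol)
        Fa[k:k + chunk] = F[:, a]
        Fb[k:k + chunk] = F[:, b]
    return Fa.reshape(grid.nx, grid.ny), Fb.reshape(grid.nx, grid.ny)


def _drift_batch(X: np.ndarray, params: CircuitParameters,
                 protocol: StimulationProtocol | None):
    """drift() vectorised over rows of an (N, 7) state batch."""
    from .circuit import _couplings, hill_response

    F = np.tile(np.asarray(params.I, float), (X.shape[0], 1)) - X / params.R
    F[:, 1] += params.D_input
    F[:, 2] -= params.D_input
    gain = np.ones(7)
    if protocol is not None:
        F[:, protocol.target_index] += protocol.soma_offset
        if protocol.mode == "decoupled":
            gain[protocol.target_index] = protocol.efferent_gain
    f = hill_response(X, params.s, params.n)
    for tgt, src, sign in _couplings(params):
        F[:, tgt - 1] += (sign * params.T[(tgt, src)] * gain[src - 1]
                          * f[:, src - 1])
    return F / params.C


def flux_field(P: ProbabilityGrid, drift2d, D_diff: float,
               floor: float = PROBABILITY_FLOOR) -> FluxField:
    """J = F P - D grad(P), central differences (one-sided at borders).

    Cells where P sits at the probability floor carry zero flux: the
    closure provides no information there.
    """
    Fx, Fy = drift2d
    if Fx.shape != P.P.shape or Fy.shape != P.P.shape:
        raise ValueError("drift field shape does not match the grid")
    grid = P.grid
    dPdx, dPdy = np.gradient(P.P, grid.dx, grid.dy, edge_order=2)
    Jx = Fx * P.P - D_diff * dPdx
    Jy = Fy * P.P - D_diff * dPdy
    at_floor = P.P <= floor * float(P.P.max())
    Jx = np.where(at_floor, 0.0, Jx)
    Jy = np.where(at_floor, 0.0, Jy)
    return FluxField(P.projection, grid, Jx, Jy, drift2d=(Fx, Fy),
                     at_floor=at_floor)


def decomposition_residual(drift2d, J: FluxField, U: LandscapeGrid,
                           P: ProbabilityGrid, D_diff: float,
                           floor: float = PROBABILITY_FLOOR):
    """Cell-wise residual of F = J/P - D grad(U).

    The identity is exact in the continuum; on the grid the residual is
    pure discretisation error and halves (roughly) when the spacing
    halves.  Floor cells and their immediate neighbours are excluded
    (their difference stencils see the clamped probability, an O(1)
    artefact); returns ``(residual_field, n_excluded)`` with NaN on
    excluded cells.
    """
    from scipy.ndimage import binary_dilation

    Fx, Fy = drift2d
    grid = P.grid
    dUdx, dUdy = np.gradient(U.U, grid.dx, grid.dy, edge_order=2)
    at_floor = P.P <= floor * float(P.P.max())
    mask = ~binary_dilation(at_floor, iterations=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        rx = Fx - (J.Jx / P.P - D_diff * dUdx)
        ry = Fy - (J.Jy / P.P - D_diff * dUdy)
    res = np.hypot(rx, ry)
    res[~mask] = np.nan
    return res, int((~mask).sum())


def _interp(grid: GridSpec, values: np.ndarray):
    return RegularGridInterpolator(
        (grid.x_centers, grid.y_centers), values,
        bounds_error=False, fill_value=None)


def _resample_closed(poly: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polyline uniformly in arc length (n points)."""
    seg = np.diff(poly, axis=0)
    ds = np.hypot(seg[:, 0], seg[:, 1])
    s = np.concatenate([[0.0], np.cumsum(ds)])
    total = s[-1]
    su = np.linspace(0.0, total, n)
    x = np.interp(su, s, poly[:, 0])
    y = np.interp(su, s, poly[:, 1])
    return np.stack([x, y], axis=1)


def barrier_height(U: LandscapeGrid, cycle: LimitCycle, projection=None):
    """(U_max, U_min, barrier) for a ring landscape.

    U_min is the minimum of U bilinearly interpolated along the
    projected cycle polyline; U_max is the maximum over grid cells
    strictly inside the cycle polygon.
    """
    if cycle is None:
        raise ValueError("no limit cycle: use mono-stable summaries instead")
    projection = projection or U.projection
    poly = cycle.projected(projection)
    ring = _resample_closed(poly, 4000)
    u_ring = _interp(U.grid, U.U)(ring)
    U_min = float(np.min(u_ring))
    min_loc = tuple(ring[int(np.argmin(u_ring))])

    grid = U.grid
    X, Y = np.meshgrid(grid.x_centers, grid.y_centers, indexing="ij")
    inside = MplPath(poly).contains_points(
        np.stack([X.ravel(), Y.ravel()], axis=1)).reshape(X.shape)
    if not inside.any():
        raise ValueError("cycle polygon encloses no grid cell; refine grid")
    U_in = np.where(inside, U.U, -np.inf)
    k = int(np.argmax(U_in))
    U_max = float(U_in.ravel()[k])
    max_loc = (float(X.ravel()[k]), float(Y.ravel()[k]))
    return U_max, U_min, U_max - U_min, max_loc, min_loc


def average_flux(J: FluxField, cycle: LimitCycle, projection=None,
                 n_points: int = 4000, signed: bool = False) -> float:
    """J_Average: loop integral of the flux along the cycle over its length.

    By default the flux *magnitude* is integrated; ``signed=True``
    integrates the tangential component instead.
    """
    if cycle is None:
        raise ValueError("no limit cycle: average flux is undefined")
    projection = projection or J.projection
    ring = _resample_closed(cycle.projected(projection), n_points)
    jx = _interp(J.grid, J.Jx)(ring)
    jy = _interp(J.grid, J.Jy)(ring)
    seg = np.diff(ring, axis=0)
    ds = np.hypot(seg[:, 0], seg[:, 1])
    mid_jx = 0.5 * (jx[:-1] + jx[1:])
    mid_jy = 0.5 * (jy[:-1] + jy[1:])
    if signed:
        tx, ty = seg[:, 0] / np.maximum(ds, 1e-300), seg[:, 1] / np.maximum(ds, 1e-300)
        integrand = mid_jx * tx + mid_jy * ty
    else:
        integrand = np.hypot(mid_jx, mid_jy)
    total = float(np.sum(integrand * ds))
    length = float(np.sum(ds))
    return total / length


def entropy_production_rate(P: ProbabilityGrid, J: FluxField, D_diff: float,
                            floor: float = PROBABILITY_FLOOR) -> float:
    """EPR = sum over cells of |J|^2 / (D P) * cell area (>= 0).

    The standard non-equilibrium dissipation functional for constant
    isotropic diffusion; zero exactly when the flux vanishes on every
    counted cell.  Cells at the probability floor are excluded.
    """
    if D_diff <= 0:
        raise ValueError("entropy production requires D_diff > 0")
    mask = P.P > floor * float(P.P.max())
    J2 = J.Jx**2 + J.Jy**2
    with np.errstate(divide="ignore", invalid="ignore"):
        dens = np.where(mask, J2 / (D_diff * P.P), 0.0)
    return float(dens.sum() * P.grid.cell_area)


def analyze_condition(params: CircuitParameters,
                      protocol: StimulationProtocol | None = None,
                      projection=("cortex", "thalamus"),
                      grid: GridSpec | None = None,
                      nx: int = 200, ny: int = 200,
                      n_snapshots: int = 200,
                      closure: str = "phase_mean"):
    """Full pipeline for one condition: probability, U, J and metrics.

    Returns ``(P, U, J, metrics)``.  In the mono-stable regime the
    ring metrics (barrier, average flux, loop length, period) are NaN
    and only the entropy production rate is reported.
    """
    from .dynamics import cycle_geometry

    P = steady_state_probability(params, protocol, projection, grid=grid,
                                 n_snapshots=n_snapshots, nx=nx, ny=ny)
    U = potential_from_probability(P)
    F2d = drift_2d_on_grid(params, P, protocol, closure=closure)
    J = flux_field(P, F2d, params.D_diff)
    epr = entropy_production_rate(P, J, params.D_diff)
    if P.cycle is not None:
        U_max, U_min, barrier, max_loc, min_loc = barrier_height(U, P.cycle)
        j_avg = average_flux(J, P.cycle)
        loop = cycle_geometry(P.cycle, projection)
        metrics = LandscapeMetrics(barrier, U_max, U_min, max_loc, min_loc,
                                   j_avg, epr, period=P.period,
                                   loop_length=loop)
    else:
        k = int(np.argmin(U.U))
        loc = (float(U.grid.x_centers[k // U.grid.ny]),
               float(U.grid.y_centers[k % U.grid.ny]))
        metrics = LandscapeMetrics(np.nan, np.nan, float(U.U.min()), loc, loc,
                                   np.nan, epr)
    return P, U, J, metrics
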