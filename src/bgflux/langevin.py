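"""Brute-force Langevin simulation: the independent stochastic oracle.

Euler–Maruyama integration of dx/dt = F(x) + zeta with additive white
noise of autocorrelation <zeta zeta'> = 2 D delta(t - t'), i.e. noise
increments of variance 2 D dt per coordinate per step.  Long-run
histograms of these trajectories give an empirical landscape against
which the Gaussian mean-field landscape is validated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .landscape import PROBABILITY_FLOOR, LandscapeGrid
from .moments import GridSpec
from .dynamics import Trajectory, resolve_projection
from .params import CircuitParameters, StimulationProtocol

__all__ = [
    "NoiseSpec",
    "simulate_langevin",
    "simulate_ensemble",
    "empirical_landscape",
    "stochastic_period",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Additive-noise specification for Euler–Maruyama runs."""

    D_diff: float
    seed: int
    dt: float = 0.01  # ms

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.D_diff < 0:
            raise ValueError("D_diff must be nonnegative")


def _em_run(x0: np.ndarray, params: CircuitParameters,
            noise: NoiseSpec, n_steps: int,
            protocol: StimulationProtocol | None,
            record_every: int, bound: float):
    """Vectorised Euler–Maruyama over an ensemble (walkers, 7)."""
    from .landscape import _drift_batch

    rng = np.random.default_rng(noise.seed)
    x = np.array(x0, dtype=float, copy=True)
    if x.ndim == 1:
        x = x[None, :]
    n_walkers = x.shape[0]
    amp = np.sqrt(2.0 * noise.D_diff * noise.dt)
    n_rec = n_steps // record_every
    out = np.empty((n_rec, n_walkers, 7))
    t_rec = np.empty(n_rec)
    k = 0
    for step in range(1, n_steps + 1):
        F = _drift_batch(x, params, protocol)
        x = x + F * noise.dt + amp * rng.standard_normal(x.shape)
        if not np.all(np.abs(x) < bound):
            raise RuntimeError(
                f"Langevin trajectory diverged (|x| >= {bound}) at "
                f"t = {step * noise.dt:.2f} ms")
        if step % record_every == 0:
            out[k] = x
            t_rec[k] = step * noise.dt
            k += 1
    return t_rec[:k], out[:k]


def simulate_langevin(x0, params: CircuitParameters, noise: NoiseSpec,
                      duration: float,
                      protocol: StimulationProtocol | None = None,
                      record_every: int = 1,
                      bound: float = 1e3) -> Trajectory:
    """Single stochastic trajectory, reproducible per seed.

    Records every ``record_every``-th step; aborts with a diagnostic if
    the state norm exceeds ``bound``.
    """
    if noise.dt > params.tau / 20:
        warnings.warn(
            f"dt = {noise.dt} ms is coarse relative to tau = {params.tau} ms; "
            "consider dt <= tau/20", stacklevel=2)
    n_steps = int(round(duration / noise.dt))
    if n_steps < 1:
        raise ValueError("duration shorter than one step")
    t, out = _em_run(np.asarray(x0, float), params, noise, n_steps,
                     protocol, record_every, bound)
    return Trajectory(t, out[:, 0, :], rtol=np.nan, atol=np.nan)


def simulate_ensemble(x0, params: CircuitParameters, noise: NoiseSpec,
                      duration: float, n_walkers: int,
                      protocol: StimulationProtocol | None = None,
                      record_every: int = 10, jitter: float = 0.05,
                      bound: float = 1e3):
    """Ensemble of trajectories from jittered copies of ``x0``.

    Returns ``(times, samples)`` with samples of shape
    (n_records, n_walkers, 7).  A small Gaussian jitter decorrelates
    the walkers' initial conditions.
    """
    rng = np.random.default_rng(noise.seed + 1)
    X0 = np.asarray(x0, float)[None, :] + jitter * rng.standard_normal(
        (n_walkers, 7))
    n_steps = int(round(duration / noise.dt))
    return _em_run(X0, params, noise, n_steps, protocol, record_every, bound)


def empirical_landscape(samples: np.ndarray, projection, grid: GridSpec,
                        burn_in: int = 0, smooth_cells: float = 0.0,
                        floor: float = PROBABILITY_FLOOR) -> LandscapeGrid:
    """U = -ln of the normalised 2-D histogram of trajectory samples.

    ``samples`` is (n_records, n_walkers, 7) or (n_records, 7);
    ``burn_in`` drops that many leading records.  Empty cells are
    handled by the probability floor.  ``smooth_cells`` > 0 applies a
    Gaussian filter of that bandwidth (in cells) to the histogram —
    the standard variance-reduction step when the histogram is used as
    a mode/ridge estimator rather than a raw density.
    """
    a, b = resolve_projection(projection)
    s = np.asarray(samples, dtype=float)
    if s.ndim == 2:
        s = s[:, None, :]
    s = s[burn_in:]
    pts = s[:, :, [a, b]].reshape(-1, 2)
    if pts.shape[0] < 1e5:
        warnings.warn(
            f"only {pts.shape[0]} post-burn-in samples; histogram "
            "landscapes want >= 1e5", stacklevel=2)
    xe = np.concatenate([grid.x_centers - grid.dx / 2,
                         [grid.x_centers[-1] + grid.dx / 2]])
    ye = np.concatenate([grid.y_centers - grid.dy / 2,
                         [grid.y_centers[-1] + grid.dy / 2]])
    H, _, _ = np.histogram2d(pts[:, 0], pts[:, 1], bins=[xe, ye])
    if smooth_cells > 0:
        from scipy.ndimage import gaussian_filter

        H = gaussian_filter(H, smooth_cells)
    mass = H.sum() * grid.cell_area
    if mass == 0:
        raise ValueError("no samples landed on the grid")
    P = H / mass
    abs_floor = floor * float(P.max())
    U = -np.log(np.maximum(P, abs_floor))
    return LandscapeGrid(tuple(projection), grid, U, floor=abs_floor)


def stochastic_period(traj: Trajectory, module: str = "cortex",
                      noise_floor: float = 10.0):
    """Dominant oscillation period from a Welch-averaged power spectrum.

    Returns ``(period, width)`` in ms, or None when no spectral peak
    rises ``noise_floor`` times above the median power (segment
    averaging makes the white-noise spectrum flat, so the threshold
    separates genuine narrowband peaks from realization noise).  The
    width is the half-power half-width of the peak in period units,
    at least one frequency bin.
    """
    from scipy.signal import welch

    i = resolve_projection([module])[0]
    x = traj.y[:, i] - traj.y[:, i].mean()
    dt = float(np.median(np.diff(traj.t)))
    nperseg = min(len(x), max(256, len(x) // 8))
    freqs, psd = welch(x, fs=1.0 / dt, nperseg=nperseg)
    psd = psd[1:]
    freqs = freqs[1:]
    med = np.median(psd)
    k = int(np.argmax(psd))
    if med <= 0 or psd[k] < noise_floor * med:
        return None
    period = 1.0 / freqs[k]
    half = psd[k] / 2
    lo = k
    while lo > 0 and psd[lo] > half:
        lo -= 1
    hi = k
    while hi < len(psd) - 1 and psd[hi] > half:
        hi += 1
    df = freqs[1] - freqs[0]
    f_lo, f_hi = max(freqs[lo], df), freqs[hi]
    width = max(abs(1.0 / f_lo - 1.0 / f_hi) / 2,
                df / freqs[k] ** 2)  # never below one bin
    return float(period), float(width)
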