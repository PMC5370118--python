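"""Deterministic dynamics: integration, fixed points, limit cycles.

The circuit has a single interior fixed point that loses stability in a
Hopf bifurcation as dopamine is lowered from the healthy level, giving
a window of sustained beta-band limit-cycle oscillations; lowering
dopamine further restabilises a (low-activity) fixed point.  This
module locates those objects and builds the dopamine phase diagram.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root
from scipy.signal import find_peaks

from .circuit import drift, jacobian
from .params import MODULE_INDEX, MODULE_NAMES, CircuitParameters, StimulationProtocol

__all__ = [
    "Trajectory",
    "FixedPointRecord",
    "LimitCycle",
    "IntegrationError",
    "CycleDetectionError",
    "integrate_trajectory",
    "find_fixed_points",
    "detect_limit_cycle",
    "scan_dopamine",
    "hopf_crossings",
    "cycle_geometry",
    "resolve_projection",
]

DEFAULT_X0 = np.ones(7)
AMPLITUDE_THRESHOLD = 1e-3   # peak-to-peak below this counts as stationary


class IntegrationError(RuntimeError):
    """Integrator failure; carries the last valid state."""

    def __init__(self, message, t=None, x=None):
        super().__init__(message)
        self.t = t
        self.x = x


class CycleDetectionError(RuntimeError):
    """Raised when oscillation peaks do not lock onto a consistent period."""


@dataclass
class Trajectory:
    """Deterministic time course: time grid (ms) and states (steps x 7)."""

    t: np.ndarray
    y: np.ndarray
    rtol: float
    atol: float

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("trajectory contains non-finite states")


@dataclass
class FixedPointRecord:
    location: np.ndarray
    eigenvalues: np.ndarray
    stability: str  # "stable" | "unstable" | "saddle"

    @property
    def leading_real_part(self) -> float:
        return float(self.eigenvalues.real.max())


@dataclass
class LimitCycle:
    """One closed period of a stable oscillation.

    ``t`` runs from 0 to the period; the first and last states coincide
    within ``closure_tol``.
    """

    t: np.ndarray
    y: np.ndarray
    period: float
    closure_tol: float = 1e-3
    envelope: pd.DataFrame = field(default=None, repr=False)

    def __post_init__(self):
        if self.period <= 0:
            raise ValueError("period must be positive")
        gap = np.max(np.abs(self.y[0] - self.y[-1]))
        if gap > self.closure_tol:
            raise ValueError(
                f"cycle endpoints differ by {gap:.2e} > closure tolerance")
        if self.envelope is None:
            self.envelope = pd.DataFrame(
                {"min": self.y.min(axis=0), "max": self.y.max(axis=0)},
                index=list(MODULE_NAMES),
            )

    def projected(self, projection) -> np.ndarray:
        """Closed (N, 2) polyline in the plane of two modules."""
        a, b = resolve_projection(projection)
        return self.y[:, [a, b]]

    def amplitude(self, module="cortex") -> float:
        i = resolve_projection([module])[0]
        return float(self.y[:, i].max() - self.y[:, i].min())


def resolve_projection(projection):
    """Map module names or zero-based indices to zero-based indices."""
    out = []
    for p in projection:
        if isinstance(p, str):
            out.append(MODULE_INDEX[p])
        else:
            out.append(int(p))
    return tuple(out)


def integrate_ode(rhs, x0, duration: float, rtol: float = 1e-7,
                  atol: float = 1e-9, t_eval=None,
                  dense_output: bool = False):
    """Shared adaptive-step solver contract (RK45).

    All deterministic integrations in the package go through this
    helper, so analytic test systems exercise exactly the same
    numerical path as the circuit.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    x0 = np.asarray(x0, dtype=float)
    sol = solve_ivp(rhs, (0.0, duration), x0, rtol=rtol, atol=atol,
                    t_eval=t_eval, dense_output=dense_output, method="RK45")
    if not sol.success:
        raise IntegrationError(sol.message, t=sol.t[-1], x=sol.y[:, -1])
    traj = Trajectory(sol.t, sol.y.T, rtol=rtol, atol=atol)
    return (traj, sol.sol) if dense_output else traj


def integrate_trajectory(x0, params: CircuitParameters, duration: float,
                         protocol: StimulationProtocol | None = None,
                         rtol: float = 1e-7, atol: float = 1e-9,
                         t_eval=None, dense_output: bool = False):
    """Adaptive-step integration of the deterministic circuit.

    Returns a :class:`Trajectory`; with ``dense_output=True`` returns
    ``(Trajectory, OdeSolution)`` for continuous interpolation.
    """
    return integrate_ode(lambda t, x: drift(x, params, protocol), x0,
                         duration, rtol=rtol, atol=atol, t_eval=t_eval,
                         dense_output=dense_output)


def _classify(eigenvalues, tol=0.0) -> str:
    re = eigenvalues.real
    if np.all(re < -tol):
        return "stable"
    if np.all(re > tol):
        return "unstable"
    return "unstable" if re.max() > tol else "saddle"


def _fixed_point_from(x0, params, protocol, tol):
    sol = root(lambda x: drift(x, params, protocol), x0,
               jac=lambda x: jacobian(x, params, protocol), tol=1e-12)
    if not sol.success or np.max(np.abs(drift(sol.x, params, protocol))) > tol:
        return None
    ev = np.linalg.eigvals(jacobian(sol.x, params, protocol))
    # saddle means mixed-sign real parts
    re = ev.real
    if np.all(re < 0):
        label = "stable"
    elif np.all(re > 0):
        label = "unstable"
    else:
        label = "saddle" if np.any(re < 0) else "unstable"
    # convention: any positive real part and some negative -> saddle is
    # still "unstable" for classification purposes of oscillation onset;
    # keep the finer label.
    return FixedPointRecord(sol.x, ev, label)


def find_fixed_points(params: CircuitParameters,
                      protocol: StimulationProtocol | None = None,
                      n_starts: int = 3, tol: float = 1e-8,
                      merge_radius: float = 1e-4,
                      extra_starts=None) -> list[FixedPointRecord]:
    """Locate fixed points from a deterministic start lattice.

    Starts are an ``n_starts``-per-axis lattice over [0, 2 I_i R] plus
    the endpoint of a relaxation from the all-ones state; duplicate
    roots are merged within ``merge_radius``.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    axes = [np.linspace(0.0, 2.0 * Ii * params.R, n_starts) for Ii in params.I]
    starts = [np.array(p) for p in itertools.product(*axes)]
    relax = integrate_trajectory(DEFAULT_X0, params, 3000.0, protocol)
    starts.append(relax.y[-1])
    if extra_starts is not None:
        starts.extend(np.asarray(s, dtype=float) for s in extra_starts)

    found: list[FixedPointRecord] = []
    for x0 in starts:
        rec = _fixed_point_from(x0, params, protocol, tol)
        if rec is None:
            continue
        if any(np.linalg.norm(rec.location - r.location) < merge_radius
               for r in found):
            continue
        found.append(rec)
    return found


def track_fixed_point(params: CircuitParameters,
                      protocol: StimulationProtocol | None = None,
                      guess=None, tol: float = 1e-8) -> FixedPointRecord | None:
    """Cheap single-root continuation helper used by parameter sweeps."""
    x0 = DEFAULT_X0 if guess is None else np.asarray(guess, dtype=float)
    rec = _fixed_point_from(x0, params, protocol, tol)
    if rec is None:
        relax = integrate_trajectory(DEFAULT_X0, params, 3000.0, protocol)
        rec = _fixed_point_from(relax.y[-1], params, protocol, tol)
    return rec


def detect_limit_cycle(params: CircuitParameters,
                       protocol: StimulationProtocol | None = None,
                       transient: float = 3000.0, record: float = 1500.0,
                       x0=None, amplitude_threshold: float = AMPLITUDE_THRESHOLD,
                       cv_tol: float = 0.01, max_transient: float = 60000.0,
                       n_points: int = 2000) -> LimitCycle | None:
    """Detect a sustained limit cycle via successive cortex maxima.

    Integrates past the transient, locates maxima of the cortex
    coordinate, and accepts a cycle when the inter-peak intervals are
    consistent (CV <= ``cv_tol``) and the envelope has stopped
    contracting.  Slowly decaying ringing (common near the Hopf
    points) triggers automatic transient extension up to
    ``max_transient``; if the amplitude still decays there, returns
    None.  Returns None when the settled peak-to-peak amplitude is
    below ``amplitude_threshold``.
    """
    if transient <= 0 or record <= 0:
        raise ValueError("transient and record must be positive")
    x = DEFAULT_X0 if x0 is None else np.asarray(x0, dtype=float)

    while True:
        warm = integrate_trajectory(x, params, transient, protocol)
        x_rec = warm.y[-1]
        traj, interp = integrate_trajectory(
            x_rec, params, record, protocol,
            t_eval=np.linspace(0.0, record, max(4096, int(record * 4))),
            dense_output=True)
        sig = traj.y[:, 0]
        amp = sig.max() - sig.min()
        if amp < amplitude_threshold:
            return None
        # envelope contraction check: compare first/last third amplitudes
        third = len(sig) // 3
        a0 = sig[:third].max() - sig[:third].min()
        a1 = sig[-third:].max() - sig[-third:].min()
        settled = a0 > 0 and abs(a1 - a0) <= 0.01 * max(a0, a1)
        if settled:
            break
        if transient >= max_transient:
            if a1 < amplitude_threshold or a1 < 0.5 * a0:
                return None  # still-decaying ringing: no sustained cycle
            break
        x = traj.y[-1]
        transient = min(2.0 * transient, max_transient)

    peaks, _ = find_peaks(sig, prominence=0.25 * amp)
    if len(peaks) < 3:
        raise CycleDetectionError(
            f"only {len(peaks)} cortex maxima in the recording window")
    # parabolic refinement: sample-grid peak times are quantized to the
    # recording step, which would alias into the period estimate
    dt_s = traj.t[1] - traj.t[0]
    t_pk = np.empty(len(peaks))
    for i, k in enumerate(peaks):
        if 0 < k < len(sig) - 1:
            denom = sig[k - 1] - 2 * sig[k] + sig[k + 1]
            shift = (0.5 * (sig[k - 1] - sig[k + 1]) / denom
                     if denom != 0 else 0.0)
            t_pk[i] = traj.t[k] + np.clip(shift, -1, 1) * dt_s
        else:
            t_pk[i] = traj.t[k]
    intervals = np.diff(t_pk)
    period = float(np.mean(intervals))
    cv = float(np.std(intervals) / period)
    if cv > cv_tol:
        raise CycleDetectionError(
            f"inter-peak interval CV {cv:.3%} exceeds {cv_tol:.0%}: "
            "failed to lock onto a cycle")

    # sample exactly one period between the last two recorded peaks
    t0, t1 = t_pk[-2], t_pk[-1]
    ts = np.linspace(t0, t1, n_points)
    y = interp(ts).T
    y[-1] = y[0]  # close the loop exactly (endpoint gap is O(solver tol))
    return LimitCycle(ts - t0, y, period=period)


def scan_dopamine(params: CircuitParameters, D_grid,
                  protocol: StimulationProtocol | None = None) -> pd.DataFrame:
    """Phase diagram over an ascending grid of dopamine levels.

    For each level: track the interior fixed point and its stability;
    where unstable, detect the limit cycle (with a transient scaled to
    the linear growth rate) and record its period and envelope.  The
    mean cortex activity is taken over one period (oscillatory) or at
    the fixed point (mono-stable).
    """
    D_grid = np.asarray(D_grid, dtype=float)
    if D_grid.size == 0:
        raise ValueError("D_grid must be nonempty")
    rows = []
    guess = None
    for D in D_grid:
        p = params.with_(D_input=float(D))
        row = {"D_input": float(D), "oscillating": False, "period": np.nan,
               "mean_cortex": np.nan, "cortex_min": np.nan,
               "cortex_max": np.nan, "leading_eig_real": np.nan,
               "error": ""}
        try:
            fp = track_fixed_point(p, protocol, guess=guess)
            if fp is not None:
                guess = fp.location
                row["leading_eig_real"] = fp.leading_real_part
            unstable = fp is not None and fp.leading_real_part > 0
            cycle = None
            if unstable:
                # transient ~ several linear e-folding times of the
                # instability, so weakly growing cycles near the Hopf
                # points are fully developed before recording
                lam = max(fp.leading_real_part, 1e-4)
                cycle = detect_limit_cycle(
                    p, protocol, transient=min(max(3000.0, 10.0 / lam), 4e4))
            if cycle is not None:
                row["oscillating"] = True
                row["period"] = cycle.period
                x1 = cycle.y[:, 0]
                row["mean_cortex"] = float(np.trapezoid(x1, cycle.t)
                                           / cycle.period)
                row["cortex_min"] = float(x1.min())
                row["cortex_max"] = float(x1.max())
            elif fp is not None:
                row["mean_cortex"] = float(fp.location[0])
                row["cortex_min"] = row["cortex_max"] = row["mean_cortex"]
        except (IntegrationError, CycleDetectionError) as exc:
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)


def hopf_crossings(params: CircuitParameters, D_lo: float, D_hi: float,
                   protocol: StimulationProtocol | None = None,
                   width: float = 1e-3, coarse: int = 41) -> list[float]:
    """Locate Hopf points by bisection on the leading eigenvalue.

    Scans [D_lo, D_hi] coarsely for sign changes of the tracked fixed
    point's leading eigenvalue real part, then bisects each bracket to
    the requested width.
    """

    guess = {}

    def lead(D):
        fp = track_fixed_point(params.with_(D_input=D), protocol,
                               guess=guess.get("x"))
        if fp is None:
            raise RuntimeError(f"lost the fixed point at D_input={D}")
        guess["x"] = fp.location
        return fp.leading_real_part

    Ds = np.linspace(D_lo, D_hi, coarse)
    vals = [lead(D) for D in Ds]
    crossings = []
    for k in range(len(Ds) - 1):
        if vals[k] == 0.0:
            crossings.append(float(Ds[k]))
            continue
        if vals[k] * vals[k + 1] < 0:
            a, b = Ds[k], Ds[k + 1]
            fa = vals[k]
            while b - a > width:
                m = 0.5 * (a + b)
                fm = lead(m)
                if fa * fm <= 0:
                    b = m
                else:
                    a, fa = m, fm
            crossings.append(0.5 * (a + b))
    return crossings


def cycle_geometry(cycle: LimitCycle, projection) -> float:
    """Arc length of the projected one-period orbit (loop length)."""
    poly = cycle.projected(projection)
    if np.max(np.abs(poly[0] - poly[-1])) > cycle.closure_tol:
        raise ValueError("projected curve is not closed")
    seg = np.diff(poly, axis=0)
    return float(np.sum(np.hypot(seg[:, 0], seg[:, 1])))
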