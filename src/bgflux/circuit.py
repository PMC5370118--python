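"""Drift and Jacobian of the seven-population rate circuit.

Each population obeys a leaky Hopfield-type rate equation

    C dx_i/dt = I_i - x_i/R + sum_j (+/-) T_{i,j} f(x_j) [+/- D_input],

with the Hill response ``f(x) = x^n / (s^n + x^n)``.  The sign pattern
encodes the anatomy: cortex and thalamus excite the striatum, the
striatal projections and both pallidal segments are GABAergic
(inhibitory), the STN is glutamatergic (excitatory), and dopamine
excites the D1 population while inhibiting the D2 population.
"""

from __future__ import annotations

import numpy as np

from .params import CircuitParameters, StimulationProtocol, warn_if_invalid

__all__ = ["hill_response", "hill_derivative", "drift", "jacobian"]


def hill_response(x, s: float, n: int):
    """Sigmoidal firing-rate response ``x^n / (s^n + x^n)``.

    Monotone increasing on x >= 0 with f(0) = 0, f(s) = 1/2 and
    f -> 1 as x -> infinity.  For x < 0 the algebraic formula is
    applied unchanged (even n makes it symmetric); callers integrating
    trajectories warn when that regime is entered.
    """
    x = np.asarray(x, dtype=float)
    xn = x**n
    return xn / (s**n + xn)


def hill_derivative(x, s: float, n: int):
    """d/dx of :func:`hill_response`: ``n s^n x^(n-1) / (s^n + x^n)^2``."""
    x = np.asarray(x, dtype=float)
    sn = s**n
    return n * sn * x ** (n - 1) / (sn + x**n) ** 2


# Signed coupling structure: (target, source, sign), one-based labels.
# The drift term of equation `target` is sign * T[target, source] * f(x_source).
_COUPLINGS = (
    (1, 6, +1),   # thalamus -> cortex
    (2, 1, +1),   # cortex -> striatum D1
    (2, 6, +1),   # thalamus -> striatum D1
    (3, 1, +1),   # cortex -> striatum D2
    (3, 6, +1),   # thalamus -> striatum D2
    (4, 7, +1),   # STN -> GPi
    (4, 2, -1),   # striatum D1 -> GPi   (direct pathway)
    (4, 5, -1),   # GPe -> GPi
    (5, 7, +1),   # STN -> GPe
    (5, 3, -1),   # striatum D2 -> GPe   (indirect pathway)
    (6, 4, -1),   # GPi -> thalamus
    (7, 1, +1),   # cortex -> STN        (hyperdirect pathway)
    (7, 5, -1),   # GPe -> STN
)


def _couplings(params: CircuitParameters):
    coup = _COUPLINGS
    if params.include_T17:
        coup = coup + ((1, 7, +1),)
    return coup


def drift(x, params: CircuitParameters,
          protocol: StimulationProtocol | None = None,
          check_validity: bool = False) -> np.ndarray:
    """Deterministic driving force F(x), length-7, in units of 1/ms.

    With a stimulation protocol, ``soma_offset`` is added inside the
    target's input bracket and, in decoupled mode, every coupling term
    sourced at the target is multiplied by ``efferent_gain``.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (7,):
        raise ValueError(f"state must have length 7, got shape {x.shape}")
    if check_validity:
        warn_if_invalid(x, params.s)

    f = hill_response(x, params.s, params.n)
    F = np.array(params.I, dtype=float) - x / params.R
    F[1] += params.D_input
    F[2] -= params.D_input

    gain = np.ones(7)
    if protocol is not None:
        F[protocol.target_index] += protocol.soma_offset
        if protocol.mode == "decoupled":
            gain[protocol.target_index] = protocol.efferent_gain

    for tgt, src, sign in _couplings(params):
        F[tgt - 1] += sign * params.T[(tgt, src)] * gain[src - 1] * f[src - 1]
    return F / params.C


def jacobian(x, params: CircuitParameters,
             protocol: StimulationProtocol | None = None) -> np.ndarray:
    """7x7 Jacobian A_ij = dF_i/dx_j of :func:`drift`.

    The diagonal carries only the leak -1/(C R) = -1/tau (no module
    couples to itself); off-diagonal entries are
    ``+/- T_ij f'(x_j) / C``.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (7,):
        raise ValueError(f"state must have length 7, got shape {x.shape}")
    fp = hill_derivative(x, params.s, params.n)
    A = np.diag(np.full(7, -1.0 / (params.C * params.R)))

    gain = np.ones(7)
    if protocol is not None and protocol.mode == "decoupled":
        gain[protocol.target_index] = protocol.efferent_gain

    for tgt, src, sign in _couplings(params):
        A[tgt - 1, src - 1] += (
            sign * params.T[(tgt, src)] * gain[src - 1] * fp[src - 1]
            / params.C
        )
    return A
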