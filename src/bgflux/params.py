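"""Circuit parameters and stimulation protocols.

The model couples seven neural populations of the basal
ganglia-thalamo-cortical motor loop, each reduced to a single
Hopfield-type rate unit:

====  ==================  =========================================
idx   name                role
====  ==================  =========================================
1     cortex              motor cortex
2     striatum_D1         striatal direct-pathway neurons (D1)
3     striatum_D2         striatal indirect-pathway neurons (D2)
4     GPi_SNr             output complex (internal pallidum / SNr)
5     GPe                 external pallidum
6     thalamus            motor thalamus
7     STN                 subthalamic nucleus
====  ==================  =========================================

Dopamine enters as a constant drive ``D_input``: excitatory on the D1
population and inhibitory (same magnitude) on the D2 population.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "MODULE_NAMES",
    "MODULE_INDEX",
    "CircuitParameters",
    "StimulationProtocol",
    "ValidityWarning",
    "load_parameters",
]

MODULE_NAMES = (
    "cortex",
    "striatum_D1",
    "striatum_D2",
    "GPi_SNr",
    "GPe",
    "thalamus",
    "STN",
)

#: name -> zero-based index
MODULE_INDEX = {name: i for i, name in enumerate(MODULE_NAMES)}

# Connection strengths keyed by (target, source), one-based module labels.
# All magnitudes are nonnegative; the excitatory/inhibitory sign of every
# term is fixed by the circuit equations themselves, not by T.
_DEFAULT_T = {
    (1, 6): 2.0,   # thalamus -> cortex (excitatory)
    (4, 7): 2.0,   # STN -> GPi (excitatory)
    (2, 1): 1.4,   # cortex -> striatum D1
    (2, 6): 1.4,   # thalamus -> striatum D1
    (3, 1): 1.4,   # cortex -> striatum D2
    (3, 6): 1.4,   # thalamus -> striatum D2
    (5, 7): 1.0,   # STN -> GPe (excitatory)
    (4, 2): 3.2,   # striatum D1 -> GPi (inhibitory, direct pathway)
    (5, 3): 3.2,   # striatum D2 -> GPe (inhibitory, indirect pathway)
    (6, 4): 3.2,   # GPi -> thalamus (inhibitory)
    (4, 5): 3.0,   # GPe -> GPi (inhibitory)
    (7, 5): 1.8,   # GPe -> STN (inhibitory)
    (7, 1): 1.8,   # cortex -> STN (excitatory, hyperdirect pathway)
    (1, 7): 1.8,   # STN -> cortex: stored for completeness, unused by
                   # default (no such term in the cortex equation)
}

_DEFAULT_I = (0.1, 0.05, 1.2, 4.4, 2.8, 2.0, 1.2)


class ValidityWarning(UserWarning):
    """Emitted when a trajectory leaves the physiologically valid regime."""


@dataclass(frozen=True)
class CircuitParameters:
    """All constants of the seven-population rate model.

    Parameters
    ----------
    T : dict
        Nonnegative connection strengths keyed by one-based
        ``(target, source)`` pairs.
    s, n : float, int
        Hill threshold and exponent of the sigmoidal response
        ``f(x) = x^n / (s^n + x^n)``.
    R : float
        Membrane resistance, identical for every module.
    tau : float
        Membrane time constant ``tau = R*C`` in ms; the capacitance is
        derived as ``C = tau / R``.
    I : tuple of float
        Constant external input per module.
    D_input : float
        Dopamine level (dimensionless); +D_input drives striatum D1,
        -D_input drives striatum D2.
    D_diff : float
        Diffusion coefficient of the additive noise, identical on all
        seven coordinates.
    include_T17 : bool
        If True, add an STN->cortex term ``+T[1,7]*f(x7)`` to the
        cortex equation (off by default; exploratory only).
    """

    T: dict = field(default_factory=lambda: dict(_DEFAULT_T))
    s: float = 2.0
    n: int = 2
    R: float = 1.67
    tau: float = 6.0
    I: tuple = _DEFAULT_I
    D_input: float = 1.0
    D_diff: float = 0.01
    include_T17: bool = False

    def __post_init__(self):
        if any(v < 0 for v in self.T.values()):
            raise ValueError("connection strengths must be nonnegative")
        if self.s <= 0:
            raise ValueError("Hill threshold s must be positive")
        if int(self.n) != self.n or self.n < 1:
            raise ValueError("Hill exponent n must be an integer >= 1")
        if self.R <= 0 or self.tau <= 0:
            raise ValueError("R and tau must be positive")
        if self.D_diff < 0:
            raise ValueError("diffusion coefficient must be nonnegative")
        if len(self.I) != 7:
            raise ValueError("exactly seven external inputs required")

    @property
    def C(self) -> float:
        """Membrane capacitance, tau / R."""
        return self.tau / self.R

    def with_(self, **kwargs) -> "CircuitParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def scaled_connection(self, target: int, source: int,
                          factor: float) -> "CircuitParameters":
        """Copy with one connection strength multiplied by ``factor``."""
        key = (target, source)
        if key not in self.T:
            raise KeyError(f"no connection T{target},{source}")
        T = dict(self.T)
        T[key] = T[key] * factor
        return self.with_(T=T)


@dataclass(frozen=True)
class StimulationProtocol:
    """Constant (DC) deep-brain-stimulation protocol.

    ``direct_inhibition`` adds a negative current ``soma_offset`` to the
    target nucleus's input, lowering its somatic activity.  ``decoupled``
    additionally multiplies every efferent coupling term whose source is
    the target by ``efferent_gain`` >= 1, modelling axonal activation
    that is decoupled from somatic inhibition.
    """

    target: str
    mode: str = "direct_inhibition"
    soma_offset: float = 0.0
    efferent_gain: float = 1.0

    def __post_init__(self):
        if self.target not in ("GPi_SNr", "GPe", "STN"):
            raise ValueError(f"invalid stimulation target {self.target!r}")
        if self.mode not in ("direct_inhibition", "decoupled"):
            raise ValueError(f"invalid stimulation mode {self.mode!r}")
        if self.soma_offset > 0:
            raise ValueError("soma_offset must be <= 0 (inhibitory)")
        if self.efferent_gain < 1:
            raise ValueError("efferent_gain must be >= 1")
        if self.mode == "direct_inhibition" and self.efferent_gain != 1:
            raise ValueError("direct_inhibition requires efferent_gain == 1")

    @property
    def target_index(self) -> int:
        """Zero-based index of the stimulated module."""
        return MODULE_INDEX[self.target]


# ---------------------------------------------------------------------------
# flat key/value parameter files


def _parse_key(key: str):
    if key.startswith("T") and "," in key:
        i, j = key[1:].split(",")
        return ("T", (int(i), int(j)))
    if key.startswith("I") and key[1:].isdigit():
        return ("I", int(key[1:]))
    return (key, None)


def load_parameters(path) -> CircuitParameters:
    """Read a flat ``key = value`` parameter file.

    Recognised keys are the field names of :class:`CircuitParameters`
    (``s``, ``n``, ``R``, ``tau``, ``D_input``, ``D_diff``,
    ``include_T17``) plus per-element forms ``T<i>,<j>`` and ``I<i>``
    with one-based module labels.  Missing keys keep their defaults;
    values are validated against the model invariants.
    """
    text = Path(path).read_text()
    T = dict(_DEFAULT_T)
    I = list(_DEFAULT_I)
    scalars = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, val = (part.strip() for part in line.split("=", 1))
        kind, sub = _parse_key(key)
        if kind == "T":
            T[sub] = float(val)
        elif kind == "I":
            I[sub - 1] = float(val)
        elif key == "n":
            scalars["n"] = int(val)
        elif key == "include_T17":
            scalars["include_T17"] = val.lower() in ("1", "true", "yes")
        elif key in ("s", "R", "tau", "D_input", "D_diff"):
            scalars[key] = float(val)
        else:
            raise ValueError(f"{path}:{lineno}: unknown parameter {key!r}")
    return CircuitParameters(T=T, I=tuple(I), **scalars)


def warn_if_invalid(x: np.ndarray, s: float) -> None:
    """Warn when activities drop below -s/10.

    The even-exponent Hill response is symmetric about zero, so
    trajectories that go substantially negative are outside the regime
    where the rate equations are physiologically meaningful.
    """
    if np.any(np.asarray(x) < -s / 10):
        warnings.warn(
            "trajectory entered x < -s/10; the rate model is not "
            "physiologically meaningful for negative activities",
            ValidityWarning,
            stacklevel=3,
        )
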