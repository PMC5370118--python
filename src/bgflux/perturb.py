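"""Global sensitivity of the landscape metrics and in-silico DBS.

Sensitivity: each labelled connection strength is perturbed one at a
time over a percent grid and the full pipeline (deterministic
classification -> moment closure -> landscape/flux metrics) is rerun.

DBS: constant (DC) somatic inhibition of GPi, GPe or STN, optionally
decoupled from an excitatory gain on the target's efferents, scanning
the stimulation strength and reporting mean target activity and the
average flux that measures oscillation strength.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .landscape import analyze_condition
from .params import MODULE_INDEX, CircuitParameters, StimulationProtocol

__all__ = [
    "CONNECTION_LABELS",
    "SensitivityResult",
    "DbsCurve",
    "sensitivity_scan",
    "dbs_direct_inhibition",
    "dbs_decoupled",
]

#: The labelled anatomical arrows scanned by default: (target, source)
#: one-based pairs keyed by a human-readable name.
CONNECTION_LABELS = {
    "cortex->striatum_D1": (2, 1),
    "cortex->striatum_D2": (3, 1),
    "striatum_D1->GPi": (4, 2),
    "striatum_D2->GPe": (5, 3),
    "GPe->GPi": (4, 5),
    "GPe->STN": (7, 5),
    "STN->GPi": (4, 7),
    "STN->GPe": (5, 7),
    "GPi->thalamus": (6, 4),
    "thalamus->cortex": (1, 6),
}


@dataclass
class SensitivityResult:
    """Metrics versus percent change of one connection strength."""

    connection: str
    table: pd.DataFrame  # columns: percent, oscillating, barrier, J_average, ...


@dataclass
class DbsCurve:
    """Metrics versus stimulation strength for one DBS protocol."""

    target: str
    mode: str
    table: pd.DataFrame


def _metrics_row(params, protocol=None, projection=("cortex", "thalamus"),
                 nx=100, ny=100, n_snapshots=100):
    """One pipeline evaluation, flattened to a dict; failures recorded."""
    try:
        P, U, J, m = analyze_condition(params, protocol, projection,
                                       nx=nx, ny=ny, n_snapshots=n_snapshots)
    except Exception as exc:  # per-point failure must not abort a scan
        return {"oscillating": False, "barrier": np.nan, "J_average": np.nan,
                "EPR": np.nan, "period": np.nan, "loop_length": np.nan,
                "error": str(exc), "_P": None}
    oscillating = P.cycle is not None
    return {
        "oscillating": oscillating,
        "barrier": m.barrier_height,
        "J_average": m.average_flux if oscillating else 0.0,
        "EPR": m.entropy_production_rate,
        "period": m.period,
        "loop_length": m.loop_length,
        "error": "",
        "_P": P,
    }


def sensitivity_scan(params: CircuitParameters, connections=None,
                     percent_grid=None, D_input: float = 0.95,
                     projection=("cortex", "thalamus"),
                     nx: int = 100, ny: int = 100,
                     n_snapshots: int = 100) -> list[SensitivityResult]:
    """Perturb each connection independently and rebuild all metrics.

    ``percent_grid`` must contain 0 (the baseline); the default is
    -50% .. +50% in 10% steps.  Connections may be given as label
    strings (see :data:`CONNECTION_LABELS`) or (target, source) pairs.
    """
    if connections is None:
        connections = list(CONNECTION_LABELS)
    if percent_grid is None:
        percent_grid = np.arange(-50, 51, 10)
    percent_grid = np.asarray(percent_grid, dtype=float)
    if not np.any(percent_grid == 0):
        raise ValueError("percent grid must include the 0% baseline")

    base = params.with_(D_input=D_input)
    baseline_row = _metrics_row(base, None, projection, nx, ny, n_snapshots)

    results = []
    for conn in connections:
        if isinstance(conn, str):
            label, (tgt, src) = conn, CONNECTION_LABELS[conn]
        else:
            tgt, src = conn
            label = next((k for k, v in CONNECTION_LABELS.items()
                          if v == (tgt, src)), f"T{tgt},{src}")
        if (tgt, src) not in base.T:
            raise KeyError(f"connection T{tgt},{src} not in parameters")
        rows = []
        for pct in percent_grid:
            if pct == 0:
                row = dict(baseline_row)  # bit-identical baseline
            else:
                p = base.scaled_connection(tgt, src, 1.0 + pct / 100.0)
                row = _metrics_row(p, None, projection, nx, ny, n_snapshots)
            row.pop("_P", None)
            row["percent"] = float(pct)
            rows.append(row)
        tab = pd.DataFrame(rows)[
            ["percent", "oscillating", "barrier", "J_average", "EPR",
             "period", "loop_length", "error"]]
        results.append(SensitivityResult(label, tab))
    return results


def _dbs_scan(params, target, protocols, D_input, projection, nx, ny,
              n_snapshots, mode):
    base = params.with_(D_input=D_input)
    tgt_idx = MODULE_INDEX[target]
    rows = []
    baseline_activity = None
    for proto in protocols:
        row = _metrics_row(base, proto, projection, nx, ny, n_snapshots)
        P = row.pop("_P")
        # attractor-mean activity of the stimulated target
        if P is None:
            act = np.nan
        elif P.cycle is not None:
            y = P.cycle.y[:, tgt_idx]
            act = float(np.trapezoid(y, P.cycle.t) / P.cycle.period)
        else:
            act = float(P.fixed_point[tgt_idx])
        if baseline_activity is None:
            baseline_activity = act
        row.update({
            "soma_offset": proto.soma_offset,
            "efferent_gain": proto.efferent_gain,
            "target_activity": act,
            "activity_drop": (baseline_activity - act
                              if np.isfinite(act) else np.nan),
        })
        if not row["oscillating"]:
            row["J_average"] = 0.0
        rows.append(row)
    tab = pd.DataFrame(rows)[
        ["soma_offset", "efferent_gain", "target_activity", "activity_drop",
         "oscillating", "barrier", "J_average", "EPR", "period",
         "loop_length", "error"]]
    return DbsCurve(target, mode, tab)


def dbs_direct_inhibition(params: CircuitParameters, target: str,
                          offsets, D_input: float = 0.9,
                          projection=("cortex", "thalamus"),
                          nx: int = 100, ny: int = 100,
                          n_snapshots: int = 100) -> DbsCurve:
    """Direct-inhibition DBS: a negative DC input to the target nucleus.

    ``offsets`` is a grid of soma offsets <= 0 beginning at 0 (the
    baseline, which must be oscillatory).
    """
    offsets = np.asarray(offsets, dtype=float)
    if offsets[0] != 0:
        raise ValueError("first offset must be 0 (the baseline)")
    protocols = [StimulationProtocol(target, "direct_inhibition",
                                     soma_offset=float(o)) for o in offsets]
    curve = _dbs_scan(params, target, protocols, D_input, projection,
                      nx, ny, n_snapshots, "direct_inhibition")
    if not curve.table.iloc[0]["oscillating"]:
        raise ValueError(
            f"baseline at D_input={D_input} is not oscillatory; DBS "
            "curves require an oscillatory starting point")
    return curve


def dbs_decoupled(params: CircuitParameters, target: str,
                  soma_offsets, efferent_gains, D_input: float = 0.9,
                  projection=("cortex", "thalamus"),
                  nx: int = 100, ny: int = 100,
                  n_snapshots: int = 100) -> DbsCurve:
    """Decoupled DBS: somatic inhibition with efferent activation.

    ``soma_offsets`` (<= 0) and ``efferent_gains`` (>= 1) are aligned
    grids; the first point must be (0, 1), the unstimulated baseline.
    """
    soma_offsets = np.asarray(soma_offsets, dtype=float)
    efferent_gains = np.asarray(efferent_gains, dtype=float)
    if soma_offsets.shape != efferent_gains.shape:
        raise ValueError("offset and gain grids must be aligned")
    if soma_offsets[0] != 0 or efferent_gains[0] != 1:
        raise ValueError("first point must be the (0, 1) baseline")
    protocols = [StimulationProtocol(target, "decoupled",
                                     soma_offset=float(o),
                                     efferent_gain=float(g))
                 for o, g in zip(soma_offsets, efferent_gains)]
    return _dbs_scan(params, target, protocols, D_input, projection,
                     nx, ny, n_snapshots, "decoupled")
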