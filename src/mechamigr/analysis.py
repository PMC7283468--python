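"""Output metrics, migration-mode classification, and study aggregation.

The six tracked metrics are the interface centre-of-mass displacement, the
FA count, actual FA lifetimes, the mean strengthening factor, the cumulative
rupture count, and the total traction — the per-substrate-triangle FA force
divided by the triangle area, summed in magnitude over the plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import SubstrateGrid
from .params import ParamSet, Condition

__all__ = [
    "TractionMap",
    "traction_map",
    "total_traction",
    "com_displacement",
    "classify_mode",
    "aggregate_study",
    "append_metrics",
    "metrics_frame",
]

#: Sliding-window length used by the progressive-motion test [s].
PROGRESSIVE_WINDOW = 4 * 3600.0
#: Minimum final displacement for a run to count as migration [m].
MIN_MIGRATION_DISPLACEMENT = 3e-6


@dataclass
class TractionMap:
    """Per-substrate-triangle traction vectors [Pa] at one instant."""

    tractions: np.ndarray      # (n_tri, 3)
    timestamp: float           # [s]
    area: float                # triangle area [m^2]


def traction_map(fas, substrate: SubstrateGrid, clock: float = 0.0) -> TractionMap:
    """Traction exerted on each substrate triangle: sum of the FA reaction
    forces on the triangle containing each anchor, divided by triangle area.

    Raises ``ValueError`` if an anchor falls outside the grid.
    """
    T = np.zeros((substrate.n_triangles, 3))
    if fas:
        anchors = np.array([fa.anchor for fa in fas])
        forces = np.array([fa.force for fa in fas])
        idx = substrate.triangle_index(anchors[:, 0], anchors[:, 1])
        # the cell pulls the node toward the anchor; the substrate feels -F
        np.add.at(T, idx, -forces)
        T /= substrate.tri_area
    return TractionMap(tractions=T, timestamp=clock, area=substrate.tri_area)


def total_traction(tmap: TractionMap) -> float:
    """|T_cell| [Pa]: the sum of traction *magnitudes* over all triangles."""
    return float(np.linalg.norm(tmap.tractions, axis=1).sum())


def com_displacement(log: pd.DataFrame) -> np.ndarray:
    """Cumulative x-displacement series [m] of the interface centre of mass.

    The cumulative sum of consecutive x-differences of the interface-node
    CoM; frames with an empty interface carry the previous CoM forward.
    """
    com = log["com_x"].to_numpy(dtype=float)
    filled = pd.Series(com).ffill().to_numpy()
    if len(filled) == 0:
        return np.empty(0)
    start = filled[~np.isnan(filled)]
    if len(start) == 0:
        return np.zeros(len(filled))
    filled = np.where(np.isnan(filled), start[0], filled)
    return np.concatenate([[0.0], np.cumsum(np.diff(filled))])


def classify_mode(log: pd.DataFrame, duration: float) -> str:
    """Classify a run as ``"collective"``, ``"progressive"`` or ``"none"``.

    Collective: at least one full-retraction event.  Progressive: the cell
    moved continuously forward — final displacement of at least 3 um and a
    positive displacement over every sliding 4 h window (window capped at
    the run duration for shorter runs).  Otherwise none; net-negative
    displacement is no migration.
    """
    if len(log) and log.get("n_retraction_events") is not None and \
            log["n_retraction_events"].iloc[-1] > 0:
        return "collective"
    disp = com_displacement(log)
    if len(disp) == 0 or disp[-1] < MIN_MIGRATION_DISPLACEMENT:
        return "none"
    t = log["time"].to_numpy(dtype=float)
    window = min(PROGRESSIVE_WINDOW, duration)
    for k in range(len(t)):
        j = np.searchsorted(t, t[k] + window)
        if j >= len(t):
            break
        if disp[j] - disp[k] <= 0:
            return "none"
    return "progressive"


def classify_state(state, duration: float) -> str:
    """Classify directly from a finished :class:`SimState`'s metrics."""
    return classify_mode(metrics_frame(state), duration)


def append_metrics(state, condition: Condition, params: ParamSet) -> None:
    """Append one metrics row for the current state (engine save hook)."""
    mesh = state.mesh
    iface = mesh.interface_node
    if iface.any():
        com_x = float(mesh.positions[iface, 0].mean())
        empty = False
    else:
        com_x = state._prev_com_x if state._prev_com_x is not None else float("nan")
        empty = True
    if state._prev_com_x is not None and not math.isnan(com_x):
        state.cum_displacement += com_x - state._prev_com_x
    if not math.isnan(com_x):
        state._prev_com_x = com_x

    tmap = traction_map(state.fas, state.substrate, state.clock)
    lifetimes = [state.clock - fa.birth_time for fa in state.fas]
    state.metrics_rows.append({
        "time": state.clock,
        "com_x": com_x,
        "cum_displacement": state.cum_displacement,
        "n_fa": len(state.fas),
        "cum_ruptures": state.cum_ruptures,
        "cum_disassemblies": state.cum_disassemblies,
        "total_traction": total_traction(tmap),
        "mean_fa_lifetime": float(np.mean(lifetimes)) if lifetimes else 0.0,
        "mean_n_str": float(np.mean([sf.n_str for sf in state.sfs]))
        if state.sfs else 0.0,
        "n_retraction_events": len(state.retraction_times),
        "interface_empty": empty,
    })


_METRIC_COLUMNS = [
    "time", "com_x", "cum_displacement", "n_fa", "cum_ruptures",
    "cum_disassemblies", "total_traction", "mean_fa_lifetime",
    "mean_n_str", "n_retraction_events", "interface_empty",
]


def metrics_frame(state) -> pd.DataFrame:
    """The state's metrics log as a DataFrame (documented column order)."""
    return pd.DataFrame(state.metrics_rows, columns=_METRIC_COLUMNS)


def aggregate_study(results: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-run results into condition x setup summary tables.

    ``results`` holds one row per finished run with columns k_ECM,
    r_off_FA0, FA_mat, SF_str, final_displacement, n_fa, fa_lifetime,
    mean_n_str, cum_ruptures, n_retraction_events, total_traction, mode.
    Returns mean and SEM over replicates per (setup, condition), the modal
    mode label, and the replicate count (flagged when below five).
    """
    value_cols = [c for c in (
        "final_displacement", "n_fa", "fa_lifetime", "mean_n_str",
        "cum_ruptures", "n_retraction_events", "total_traction",
    ) if c in results.columns]
    keys = ["FA_mat", "SF_str", "k_ECM", "r_off_FA0"]
    rows = []
    for key_vals, grp in results.groupby(keys, sort=True):
        row = dict(zip(keys, key_vals))
        n = len(grp)
        row["n_reps"] = n
        row["underpowered"] = n < 5
        for c in value_cols:
            vals = grp[c].to_numpy(dtype=float)
            row[f"{c}_mean"] = vals.mean()
            row[f"{c}_sem"] = vals.std(ddof=1) / math.sqrt(n) if n > 1 else 0.0
        if "mode" in grp:
            row["mode"] = grp["mode"].mode().iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)
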