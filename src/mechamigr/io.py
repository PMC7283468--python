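"""File output: VTK legacy polydata frames, OFF export, CSV logs, and
HDF5 checkpoints of the full simulation state."""

from __future__ import annotations

import os

import numpy as np

from .geometry import CellMesh, SubstrateGrid

__all__ = [
    "write_vtk_polydata",
    "write_cell_frame",
    "write_off",
    "write_events_csv",
    "save_checkpoint",
    "load_checkpoint_arrays",
]


def write_vtk_polydata(path, points, polygons=None, lines=None,
                       point_data=None, cell_data=None, title="mechamigr"):
    """Minimal legacy-ASCII VTK polydata writer (points/polygons/lines plus
    scalar data arrays)."""
    points = np.asarray(points, dtype=float)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"{title}\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(points)} double\n")
        for p in points:
            fh.write(f"{p[0]:.9e} {p[1]:.9e} {p[2]:.9e}\n")
        if polygons is not None and len(polygons):
            polygons = np.asarray(polygons, dtype=int)
            n, k = polygons.shape
            fh.write(f"POLYGONS {n} {n * (k + 1)}\n")
            for poly in polygons:
                fh.write(f"{k} " + " ".join(map(str, poly)) + "\n")
        if lines is not None and len(lines):
            lines = np.asarray(lines, dtype=int)
            n = len(lines)
            fh.write(f"LINES {n} {n * 3}\n")
            for a, b in lines:
                fh.write(f"2 {a} {b}\n")
        if point_data:
            fh.write(f"POINT_DATA {len(points)}\n")
            _write_arrays(fh, point_data)
        if cell_data:
            n_cells = (len(polygons) if polygons is not None else 0) + \
                (len(lines) if lines is not None else 0)
            fh.write(f"CELL_DATA {n_cells}\n")
            _write_arrays(fh, cell_data)


def _write_arrays(fh, arrays: dict):
    for name, arr in arrays.items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim == 1:
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            fh.write("\n".join(f"{v:.9e}" for v in arr) + "\n")
        else:
            fh.write(f"VECTORS {name} double\n")
            for v in arr:
                fh.write(f"{v[0]:.9e} {v[1]:.9e} {v[2]:.9e}\n")


def write_cell_frame(path, state, params):
    """Cell mesh with region labels and actin concentration as VTK polydata."""
    mesh = state.mesh
    write_vtk_polydata(
        path, mesh.positions, polygons=mesh.triangles,
        cell_data={"region": mesh.region.astype(float), "G": state.field.G},
    )


def write_off(path, mesh: CellMesh):
    """OFF export of the cortex mesh."""
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{mesh.n_nodes} {mesh.n_triangles} 0\n")
        for p in mesh.positions:
            fh.write(f"{p[0]:.9e} {p[1]:.9e} {p[2]:.9e}\n")
        for t in mesh.triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")


def write_events_csv(path, events):
    """FA event log as CSV (time, node, event, force, region)."""
    import pandas as pd
    rows = [{"time": e.time, "node": e.node_id, "event": e.kind,
             "force_N": e.force_mag, "region": e.region_tag} for e in events]
    pd.DataFrame(rows, columns=["time", "node", "event", "force_N",
                                "region"]).to_csv(path, index=False)


def save_checkpoint(path, state):
    """Full SimState arrays to an HDF5 container (positions, velocities,
    field, FA/SF tables, clock, rng state)."""
    import h5py
    import pickle

    with h5py.File(path, "w") as h5:
        h5.attrs["clock"] = state.clock
        h5.create_dataset("positions", data=state.mesh.positions)
        h5.create_dataset("velocities", data=state.mesh.velocities)
        h5.create_dataset("G", data=state.field.G)
        h5.create_dataset("region", data=state.mesh.region)
        h5.create_dataset("refractory", data=state.refractory.timers)
        if state.fas:
            h5.create_dataset("fa_nodes",
                              data=np.array([fa.node_id for fa in state.fas]))
            h5.create_dataset("fa_anchors",
                              data=np.array([fa.anchor for fa in state.fas]))
            h5.create_dataset("fa_birth",
                              data=np.array([fa.birth_time for fa in state.fas]))
            h5.create_dataset("fa_uid",
                              data=np.array([fa.uid for fa in state.fas]))
        h5.attrs["rng_state"] = np.void(pickle.dumps(state.rng.bit_generator.state))


def load_checkpoint_arrays(path) -> dict:
    """Read back a checkpoint's raw arrays (reconstruction helper)."""
    import h5py
    out = {}
    with h5py.File(path, "r") as h5:
        out["clock"] = float(h5.attrs["clock"])
        for key in h5.keys():
            out[key] = np.asarray(h5[key])
    return out
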