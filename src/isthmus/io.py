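"""Artifact export: legacy-VTK fields, HDF5 checkpoints, CSV traces, JSON
region sets.

Field snapshots are written as legacy-VTK ASCII structured points (readable
by ParaView/VisIt); full state checkpoints go to HDF5 with provenance
attributes; site traces and tables to CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "write_vtk_fields",
    "write_regions_json",
    "save_checkpoint",
    "load_checkpoint",
    "write_trace_csv",
]


def write_vtk_fields(path, grid, fields: dict[str, np.ndarray]) -> None:
    """Write per-node scalar fields on the lattice as a legacy-VTK ASCII
    structured-points dataset.

    Each field is either full-lattice ``(nx, ny)`` or flat over a node subset
    given as ``(values, flat_indices)``; missing nodes are filled with NaN.
    """
    nx, ny = grid.shape
    lines = [
        "# vtk DataFile Version 3.0",
        "isthmus field snapshot",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} 1",
        "ORIGIN 0 0 0",
        f"SPACING {grid.spacing} {grid.spacing} 1",
        f"POINT_DATA {nx * ny}",
    ]
    out = {}
    out["label"] = grid.labels.astype(float)
    for name, val in fields.items():
        if isinstance(val, tuple):
            arr = np.full(nx * ny, np.nan)
            arr[val[1]] = val[0]
            out[name] = arr.reshape(nx, ny)
        else:
            out[name] = np.asarray(val, dtype=float)
    for name, arr in out.items():
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        # VTK structured points iterate x fastest
        flat = arr.T.ravel()
        lines.extend(" ".join(f"{v:.6g}" for v in flat[i : i + 9])
                     for i in range(0, len(flat), 9))
    Path(path).write_text("\n".join(lines) + "\n")


def write_regions_json(path, grid) -> None:
    """Named node-sets as JSON lists of flat indices."""
    data = {k: np.asarray(v).tolist() for k, v in grid.regions.items()}
    Path(path).write_text(json.dumps(data))


def save_checkpoint(path, state, provenance: dict | None = None) -> None:
    """Full tissue state (V_m, eta, t, phi_e) to HDF5 with a provenance JSON
    attribute."""
    with h5py.File(path, "w") as f:
        f.create_dataset("vm", data=state.vm)
        f.create_dataset("eta", data=state.eta)
        f.attrs["t"] = state.t
        if state.phi_e is not None:
            f.create_dataset("phi_e", data=state.phi_e)
        if provenance is not None:
            f.attrs["provenance"] = json.dumps(provenance, default=str)


def load_checkpoint(path):
    """Load an HDF5 checkpoint; returns ``(TissueState, provenance dict)``."""
    from .solver import TissueState

    with h5py.File(path, "r") as f:
        st = TissueState(
            f["vm"][...],
            f["eta"][...],
            float(f.attrs["t"]),
            f["phi_e"][...] if "phi_e" in f else None,
        )
        prov = json.loads(f.attrs.get("provenance", "{}"))
    return st, prov


def write_trace_csv(path, t, vm, header=("t_ms", "vm_mV")) -> None:
    np.savetxt(
        path,
        np.column_stack([t, vm]),
        delimiter=",",
        header=",".join(header),
        comments="",
    )
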