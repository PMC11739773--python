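"""Model I/O: CARP-style text meshes and legacy-VTK ASCII export.

A model directory holds `model.pts` (node coordinates, mm), `model.elem`
(simplices with an integer tissue tag: 0 healthy, 1 border zone, 2 core)
and `model.lon` (per-element fiber vectors) in the plain-text format used
by cardiac simulation toolchains, plus an optional `aha.dat` segment map.
The VTK writer emits a legacy ASCII unstructured grid with tissue, fiber
and segment cell data for visualization.
"""

from __future__ import annotations

import json
import os
from typing import Optional

import numpy as np

from .model import VentricularModel


def write_carp(model: VentricularModel, out_dir: str, basename: str = "model") -> None:
    os.makedirs(out_dir, exist_ok=True)
    pts = os.path.join(out_dir, f"{basename}.pts")
    with open(pts, "w") as f:
        f.write(f"{model.n_nodes}\n")
        for x, y, z in model.nodes:
            f.write(f"{x:.6f} {y:.6f} {z:.6f}\n")
    tag = "Tr" if model.dim == 2 else "Tt"
    with open(os.path.join(out_dir, f"{basename}.elem"), "w") as f:
        f.write(f"{model.n_elements}\n")
        for el, t in zip(model.elements, model.tissue):
            f.write(f"{tag} " + " ".join(map(str, el)) + f" {t}\n")
    if model.fibers is not None:
        with open(os.path.join(out_dir, f"{basename}.lon"), "w") as f:
            f.write("1\n")
            for fx, fy, fz in model.fibers:
                f.write(f"{fx:.6f} {fy:.6f} {fz:.6f}\n")
    if model.aha is not None:
        np.savetxt(
            os.path.join(out_dir, "aha.dat"), model.aha, fmt="%d"
        )
    meta = {
        "kind": model.kind,
        "node_sets": {k: np.asarray(v).tolist() for k, v in model.node_sets.items()},
    }
    if model.transmural is not None:
        meta["has_transmural"] = True
        np.savetxt(
            os.path.join(out_dir, "transmural.dat"), model.transmural, fmt="%.6f"
        )
    with open(os.path.join(out_dir, "meta.json"), "w") as f:
        json.dump(meta, f)


def read_carp(model_dir: str, basename: str = "model") -> VentricularModel:
    pts = np.loadtxt(os.path.join(model_dir, f"{basename}.pts"), skiprows=1)
    elem_path = os.path.join(model_dir, f"{basename}.elem")
    elements, tissue = [], []
    with open(elem_path) as f:
        n = int(f.readline())
        for _ in range(n):
            parts = f.readline().split()
            k = 3 if parts[0] == "Tr" else 4
            elements.append([int(p) for p in parts[1: 1 + k]])
            tissue.append(int(parts[1 + k]))
    fibers = None
    lon_path = os.path.join(model_dir, f"{basename}.lon")
    if os.path.exists(lon_path):
        fibers = np.loadtxt(lon_path, skiprows=1)
    kind = "generic"
    node_sets = {}
    transmural = None
    meta_path = os.path.join(model_dir, "meta.json")
    if os.path.exists(meta_path):
        with open(meta_path) as f:
            meta = json.load(f)
        kind = meta.get("kind", "generic")
        node_sets = {
            k: np.asarray(v, dtype=np.int64) for k, v in meta.get("node_sets", {}).items()
        }
        if meta.get("has_transmural"):
            transmural = np.loadtxt(os.path.join(model_dir, "transmural.dat"))
    aha = None
    aha_path = os.path.join(model_dir, "aha.dat")
    if os.path.exists(aha_path):
        aha = np.loadtxt(aha_path, dtype=np.int64)
    return VentricularModel(
        nodes=np.atleast_2d(pts),
        elements=np.asarray(elements, dtype=np.int64),
        tissue=np.asarray(tissue, dtype=np.int64),
        fibers=fibers,
        aha=aha,
        transmural=transmural,
        kind=kind,
        node_sets=node_sets,
    )


_VTK_CELL = {3: 5, 4: 10}  # triangle, tetrahedron


def write_vtk(
    model: VentricularModel,
    path: str,
    point_data: Optional[dict] = None,
    cell_data: Optional[dict] = None,
) -> None:
    """Legacy-VTK ASCII unstructured grid with tissue/fiber/AHA cell data."""
    cd = {"tissue": model.tissue}
    if model.fibers is not None:
        cd["fibers"] = model.fibers
    if model.aha is not None:
        cd["aha"] = model.aha
    if cell_data:
        cd.update(cell_data)
    pd_ = dict(point_data or {})
    if model.transmural is not None:
        pd_.setdefault("transmural", model.transmural)

    k = model.elements.shape[1]
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nventricular model\nASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {model.n_nodes} float\n")
        for x, y, z in model.nodes:
            f.write(f"{x:.6f} {y:.6f} {z:.6f}\n")
        f.write(f"CELLS {model.n_elements} {model.n_elements * (k + 1)}\n")
        for el in model.elements:
            f.write(f"{k} " + " ".join(map(str, el)) + "\n")
        f.write(f"CELL_TYPES {model.n_elements}\n")
        f.write("\n".join([str(_VTK_CELL[k])] * model.n_elements) + "\n")
        if pd_:
            f.write(f"POINT_DATA {model.n_nodes}\n")
            for name, arr in pd_.items():
                _write_vtk_array(f, name, np.asarray(arr))
        if cd:
            f.write(f"CELL_DATA {model.n_elements}\n")
            for name, arr in cd.items():
                _write_vtk_array(f, name, np.asarray(arr))


def _write_vtk_array(f, name: str, arr: np.ndarray) -> None:
    if arr.ndim == 1:
        if np.issubdtype(arr.dtype, np.integer):
            f.write(f"SCALARS {name} int 1\nLOOKUP_TABLE default\n")
            f.write("\n".join(str(int(v)) for v in arr.tolist()) + "\n")
        else:
            finite = np.where(np.isfinite(arr), arr, -1.0)
            f.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            f.write("\n".join(f"{v:.6f}" for v in finite.tolist()) + "\n")
    else:
        finite = np.where(np.isfinite(arr), arr, -1.0)
        f.write(f"VECTORS {name} float\n")
        for row in finite:
            f.write(" ".join(f"{v:.6f}" for v in row) + "\n")


def write_activation_csv(times: np.ndarray, path: str) -> None:
    with open(path, "w") as f:
        f.write("node_id,T_ms\n")
        for i, t in enumerate(times):
            f.write(f"{i},{'inf' if not np.isfinite(t) else f'{t:.4f}'}\n")


def read_intensity_csv(path: str, n_nodes: int) -> np.ndarray:
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    out = np.zeros(n_nodes)
    out[data[:, 0].astype(int)] = data[:, 1]
    return out
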