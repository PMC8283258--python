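"""File formats: meshes (STL/PLY/legacy VTK polydata), masks, labels, manifests.

Patient meshes follow the naming convention ``<id>_epi.*``, ``<id>_endo.*``,
``<id>_scar.*`` plus an optional ``<id>_valves.json`` with marker points, or
a JSON manifest listing the files explicitly.  Masks are written as 8-bit
PNGs (0/255) plus one compressed ``.npz`` archive per patient; labels and
exclusion reasons go to a per-patient CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
from PIL import Image

from .geometry import LVMesh

__all__ = [
    "load_surface",
    "save_surface",
    "load_patient_meshes",
    "save_patient_meshes",
    "save_masks",
    "load_masks",
    "save_labels_csv",
    "load_labels_csv",
]

LABEL_COLUMNS = ["patient_id", "slice_index", "normalized_position", "label", "valid", "reason"]


def load_surface(path) -> tuple:
    """(vertices, faces) from STL, PLY or legacy ASCII VTK polydata."""
    path = Path(path)
    if path.suffix.lower() == ".vtk":
        return _read_vtk_polydata(path)
    tm = trimesh.load(str(path), force="mesh")
    return np.asarray(tm.vertices, dtype=float), np.asarray(tm.faces, dtype=np.int64)


def save_surface(path, vertices, faces) -> None:
    path = Path(path)
    if path.suffix.lower() == ".vtk":
        _write_vtk_polydata(path, vertices, faces)
        return
    trimesh.Trimesh(vertices, faces, process=False).export(str(path))


def _read_vtk_polydata(path: Path) -> tuple:
    """Minimal legacy ASCII VTK polydata reader (POINTS + POLYGONS)."""
    tokens = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    verts = faces = None
    while i < len(lines):
        parts = lines[i].split()
        if parts and parts[0] == "POINTS":
            n = int(parts[1])
            vals = []
            i += 1
            while len(vals) < 3 * n:
                vals.extend(float(t) for t in lines[i].split())
                i += 1
            verts = np.array(vals).reshape(n, 3)
            continue
        if parts and parts[0] == "POLYGONS":
            n = int(parts[1])
            vals = []
            i += 1
            while len(vals) < n and i < len(lines):
                row = [int(t) for t in lines[i].split()]
                if row:
                    if row[0] != 3:
                        raise ValueError("only triangulated polydata is supported")
                    vals.append(row[1:4])
                i += 1
            faces = np.array(vals, dtype=np.int64)
            continue
        i += 1
    if verts is None or faces is None:
        raise ValueError(f"{path} is not a legacy VTK polydata file")
    return verts, faces


def _write_vtk_polydata(path: Path, vertices, faces) -> None:
    v = np.asarray(vertices, dtype=float)
    f = np.asarray(faces, dtype=np.int64)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nlvscar surface\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(v)} float\n")
        for p in v:
            fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
        fh.write(f"POLYGONS {len(f)} {4 * len(f)}\n")
        for tri in f:
            fh.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n")


def save_patient_meshes(directory, mesh: LVMesh, fmt: str = "ply") -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pid = mesh.patient_id
    save_surface(directory / f"{pid}_epi.{fmt}", mesh.epi_vertices, mesh.epi_faces)
    save_surface(directory / f"{pid}_endo.{fmt}", mesh.endo_vertices, mesh.endo_faces)
    if mesh.has_scar:
        save_surface(directory / f"{pid}_scar.{fmt}", mesh.scar_vertices, mesh.scar_faces)
    if mesh.valve_points is not None:
        with open(directory / f"{pid}_valves.json", "w") as fh:
            json.dump({"valve_points": np.asarray(mesh.valve_points).tolist()}, fh)


def load_patient_meshes(directory, patient_id: str) -> LVMesh:
    directory = Path(directory)

    def find(kind):
        for ext in ("ply", "stl", "vtk"):
            p = directory / f"{patient_id}_{kind}.{ext}"
            if p.exists():
                return p
        return None

    epi, endo = find("epi"), find("endo")
    if epi is None or endo is None:
        raise FileNotFoundError(f"missing epi/endo surfaces for {patient_id} in {directory}")
    ev, ef = load_surface(epi)
    nv, nf = load_surface(endo)
    sv = sf = None
    scar = find("scar")
    if scar is not None:
        sv, sf = load_surface(scar)
    vp = None
    vpath = directory / f"{patient_id}_valves.json"
    if vpath.exists():
        with open(vpath) as fh:
            vp = np.asarray(json.load(fh)["valve_points"], dtype=float)
    return LVMesh(
        patient_id=patient_id,
        epi_vertices=ev, epi_faces=ef,
        endo_vertices=nv, endo_faces=nf,
        scar_vertices=sv, scar_faces=sf,
        valve_points=vp,
    )


def save_masks(directory, masks, patient_id: str, write_png: bool = True) -> None:
    """Per-slice PNGs plus one compressed archive per patient."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    grids = {}
    for m in masks:
        name = f"{patient_id}_slice{m.slice_index:02d}"
        grids[name] = m.grid
        if write_png:
            Image.fromarray((m.grid * 255).astype(np.uint8)).save(directory / f"{name}.png")
    np.savez_compressed(directory / f"{patient_id}_masks.npz", **grids)


def load_masks(directory, patient_id: str) -> dict:
    with np.load(Path(directory) / f"{patient_id}_masks.npz") as z:
        return {k: z[k] for k in z.files}


def save_labels_csv(path, samples, patient_id: str) -> None:
    rows = [
        {
            "patient_id": patient_id,
            "slice_index": s.mask.slice_index,
            "normalized_position": s.mask.normalized_position,
            "label": s.label,
            "valid": s.valid,
            "reason": s.reason,
        }
        for s in samples
    ]
    pd.DataFrame(rows, columns=LABEL_COLUMNS).to_csv(path, index=False)


def load_labels_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
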