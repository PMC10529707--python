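"""Plain-text export of fields, meshes and schedules.

Snapshots go to legacy ASCII VTK structured-points files (readable by
ParaView/VisIt); anatomies to Wavefront OBJ (one frame per file) plus a JSON
sidecar carrying the patch labels, Fourier coefficients and period; schedules
and metric tables to CSV.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .anatomy import LASurfaceMesh
from .grid import CartesianGrid

__all__ = ["write_vtk", "write_mesh_obj", "write_mesh_json", "read_mesh_json",
           "sha256_of", "write_manifest"]


def write_vtk(path, grid: CartesianGrid, scalars: dict | None = None,
              vectors: dict | None = None, title: str = "atriaflow snapshot"):
    """Write cell-centered fields as an ASCII legacy-VTK structured-points file."""
    scalars = scalars or {}
    vectors = vectors or {}
    n = grid.n + (1,) * (3 - grid.dim)
    origin = tuple(grid.origin) + (0.0,) * (3 - grid.dim)
    npts = int(np.prod(n))
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write(f"{title}\n")
        f.write("ASCII\nDATASET STRUCTURED_POINTS\n")
        f.write(f"DIMENSIONS {n[0]} {n[1]} {n[2]}\n")
        f.write(f"ORIGIN {origin[0] + grid.h / 2} {origin[1] + grid.h / 2} "
                f"{origin[2] + (grid.h / 2 if grid.dim == 3 else 0.0)}\n")
        f.write(f"SPACING {grid.h} {grid.h} {grid.h}\n")
        f.write(f"POINT_DATA {npts}\n")
        for name, arr in scalars.items():
            f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            flat = np.asarray(arr).reshape(grid.n).transpose().ravel()
            np.savetxt(f, flat.reshape(-1, 1), fmt="%.8g")
        for name, arr in vectors.items():
            a = np.asarray(arr)
            comps = [a[..., d].reshape(grid.n).transpose().ravel()
                     for d in range(grid.dim)]
            while len(comps) < 3:
                comps.append(np.zeros_like(comps[0]))
            f.write(f"VECTORS {name} double\n")
            np.savetxt(f, np.stack(comps, axis=1), fmt="%.8g")


def write_mesh_obj(path, mesh: LASurfaceMesh, t: float):
    """One surface frame as Wavefront OBJ (2D polylines become line elements)."""
    x = mesh.positions(t)
    with open(path, "w") as f:
        f.write(f"# atriaflow surface frame at t={t:.6f} s\n")
        for p in x:
            coords = " ".join(f"{c:.8g}" for c in p) + (" 0" if mesh.dim == 2 else "")
            f.write(f"v {coords}\n")
        if mesh.dim == 2:
            for a, b in mesh.faces:
                f.write(f"l {a + 1} {b + 1}\n")
        else:
            for a, b, c in mesh.faces:
                f.write(f"f {a + 1} {b + 1} {c + 1}\n")


def write_mesh_json(path, mesh: LASurfaceMesh):
    """Full mesh description (Fourier coefficients, labels, planes)."""
    doc = {
        "period": mesh.period,
        "dim": mesh.dim,
        "coeffs": mesh.coeffs.tolist(),
        "faces": mesh.faces.tolist(),
        "patch_labels": list(map(str, mesh.patch_labels)),
        "veins": [{"name": v.name, "kind": v.kind, "direction": list(v.d),
                   "radius": v.radius, "length": v.length, "side": v.side}
                  for v in mesh.veins],
        "mv": None if mesh.mv is None else {
            "name": mesh.mv.name, "kind": "mv", "direction": list(mesh.mv.d),
            "radius": mesh.mv.radius, "length": mesh.mv.length},
        "laa": None if mesh.laa is None else {
            "name": mesh.laa.name, "kind": "laa", "direction": list(mesh.laa.d),
            "radius": mesh.laa.radius, "length": mesh.laa.length},
        "ostium_point": None if mesh.ostium_point is None else mesh.ostium_point.tolist(),
        "ostium_normal": None if mesh.ostium_normal is None else mesh.ostium_normal.tolist(),
        "fit_residual": mesh.fit_residual,
    }
    Path(path).write_text(json.dumps(doc))


def read_mesh_json(path) -> LASurfaceMesh:
    from .anatomy import TubeSpec
    doc = json.loads(Path(path).read_text())

    def spec(d):
        return None if d is None else TubeSpec(d["name"], d["kind"], tuple(d["direction"]),
                                               d["radius"], d["length"], d.get("side"))

    return LASurfaceMesh(
        coeffs=np.asarray(doc["coeffs"], dtype=float),
        faces=np.asarray(doc["faces"], dtype=int),
        patch_labels=np.asarray(doc["patch_labels"], dtype=object),
        period=doc["period"],
        veins=tuple(spec(v) for v in doc["veins"]),
        mv=spec(doc["mv"]), laa=spec(doc["laa"]),
        ostium_point=None if doc["ostium_point"] is None else np.asarray(doc["ostium_point"]),
        ostium_normal=None if doc["ostium_normal"] is None else np.asarray(doc["ostium_normal"]),
        fit_residual=doc["fit_residual"],
    )


def sha256_of(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(path, entries: dict):
    Path(path).write_text(json.dumps(entries, indent=2, sort_keys=True, default=str))
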