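"""Partition of the atrial interior into PV-adjacent, body and appendage regions.

The chamber interior is split with an intrinsic coordinate xi built on the
mitral-valve plane: planes parallel to the MV sweep the chamber from xi = 0 at
the centroid of the PV inlet caps to xi = 1 at the MV centroid.  Cells with
xi below a cutoff belong to the PV-adjacent region (LAPV); the appendage
(LAA) is everything on the sac side of the ostium plane; the remainder of the
interior is the atrial body (LAb).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anatomy import LASurfaceMesh, evaluate_mesh

__all__ = ["RegionMasks", "fit_mv_plane", "xi_coordinate", "partition",
           "interior_mask", "mv_boundary_points"]

LAPV, LAB, LAA, EXTERIOR = "LAPV", "LAb", "LAA", "exterior"


@dataclass
class RegionMasks:
    """Per-cell region labels on a Cartesian grid of cell centers."""

    labels: np.ndarray           # str array, one of {LAPV, LAb, LAA, exterior}
    xi: np.ndarray               # dimensionless axial coordinate
    mv_point: np.ndarray
    mv_normal: np.ndarray
    ostium_point: np.ndarray | None
    ostium_normal: np.ndarray | None

    def mask(self, name: str) -> np.ndarray:
        return self.labels == name

    @property
    def interior(self) -> np.ndarray:
        return self.labels != EXTERIOR


def fit_mv_plane(points: np.ndarray):
    """Total-least-squares plane (line in 2D) through the MV boundary points.

    Returns ``(point, unit_normal)`` minimizing the orthogonal squared
    distance; the normal is the singular direction of smallest variance.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < pts.shape[1]:
        raise ValueError("need at least dim points to fit the MV plane")
    c = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - c, full_matrices=False)
    if s[-2] < 1e-12 * max(1.0, s[0]):
        raise ValueError("MV points are collinear; plane is undetermined")
    return c, vt[-1]


def mv_boundary_points(mesh: LASurfaceMesh, t: float) -> np.ndarray:
    """Vertices of the mitral orifice patch at time t."""
    f = mesh.patch_faces("MV")
    if len(f) == 0:
        raise ValueError("mesh has no MV patch")
    return mesh.positions(t)[np.unique(f.ravel())]


def xi_coordinate(points: np.ndarray, cm_pvs: np.ndarray, cm_mv: np.ndarray,
                  normal: np.ndarray) -> np.ndarray:
    """Affine coordinate along the MV normal: 0 at the PV-inlet centroid, 1 at
    the MV centroid."""
    denom = float((cm_mv - cm_pvs) @ normal)
    if abs(denom) < 1e-12:
        raise ValueError("PV and MV centroids coincide along the MV normal")
    return ((points - cm_pvs) @ normal) / denom


def interior_mask(points: np.ndarray, mesh: LASurfaceMesh, t: float) -> np.ndarray:
    """Points inside the closed surface (even-odd / ray parity)."""
    x = mesh.positions(t)
    if mesh.dim == 2:
        from shapely import Polygon, contains_xy
        # vertices are ordered around the boundary
        poly = Polygon(x)
        return contains_xy(poly, points[:, 0], points[:, 1])
    return _ray_parity_3d(np.asarray(points, dtype=float), x, mesh.faces)


def _ray_parity_3d(points: np.ndarray, verts: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Even-odd containment by casting +z rays, bucketed over (x, y)."""
    # a tiny deterministic shift avoids rays through triangle edges/vertices
    pts = points + np.array([1.3e-9, 2.7e-9, 0.0])
    tri = verts[faces]
    lo = pts[:, :2].min(axis=0)
    hi = pts[:, :2].max(axis=0)
    nb = 128
    w = np.maximum((hi - lo) / nb, 1e-12)
    bi = np.clip(((pts[:, :2] - lo) / w).astype(int), 0, nb - 1)
    flat = bi[:, 0] * nb + bi[:, 1]
    order = np.argsort(flat, kind="stable")
    sorted_flat = flat[order]
    bucket_ids = np.arange(nb * nb)
    starts = np.searchsorted(sorted_flat, bucket_ids)
    ends = np.searchsorted(sorted_flat, bucket_ids, side="right")
    crossings = np.zeros(len(pts), dtype=np.int64)
    for f in tri:
        v0 = f[1] - f[0]
        v1 = f[2] - f[0]
        det = v0[0] * v1[1] - v0[1] * v1[0]
        if abs(det) < 1e-14:  # vertical triangle: measure-zero for the ray
            continue
        t0 = np.clip(((f[:, :2].min(axis=0) - lo) / w).astype(int), 0, nb - 1)
        t1 = np.clip(((f[:, :2].max(axis=0) - lo) / w).astype(int), 0, nb - 1)
        cand = [order[starts[bx * nb + by]:ends[bx * nb + by]]
                for bx in range(t0[0], t1[0] + 1)
                for by in range(t0[1], t1[1] + 1)]
        cand = np.concatenate(cand) if cand else np.empty(0, dtype=int)
        if len(cand) == 0:
            continue
        d = pts[cand, :2] - f[0, :2]
        u = (d[:, 0] * v1[1] - d[:, 1] * v1[0]) / det
        v = (v0[0] * d[:, 1] - v0[1] * d[:, 0]) / det
        inside = (u >= 0) & (v >= 0) & (u + v <= 1)
        if not inside.any():
            continue
        z_hit = f[0, 2] + u[inside] * v0[2] + v[inside] * v1[2]
        above = z_hit > pts[cand[inside], 2]
        np.add.at(crossings, cand[inside][above], 1)
    return (crossings % 2) == 1


def partition(points: np.ndarray, mesh: LASurfaceMesh, t: float,
              xi_cut: float = 0.25, use_mean_mv_plane: bool = False,
              inside: np.ndarray | None = None) -> RegionMasks:
    """Label grid points as LAPV / LAb / LAA / exterior at time t.

    The MV plane is fitted to the instantaneous orifice boundary (or to its
    cycle-mean when ``use_mean_mv_plane``); the PV centroid is the area-
    weighted centroid of the inlet caps.  ``inside`` may carry a precomputed
    interior mask to avoid repeating the point-in-surface test.
    """
    pts = np.asarray(points, dtype=float)
    if use_mean_mv_plane:
        samples = np.concatenate([mv_boundary_points(mesh, tk)
                                  for tk in np.linspace(0, mesh.period, 8, endpoint=False)])
        mv_point, mv_normal = fit_mv_plane(samples)
    else:
        mv_point, mv_normal = fit_mv_plane(mv_boundary_points(mesh, t))
    frame = evaluate_mesh(mesh, t)
    areas = np.array([frame.patch_area[v.name] for v in mesh.veins])
    cents = np.array([frame.patch_centroid[v.name] for v in mesh.veins])
    cm_pvs = (areas[:, None] * cents).sum(axis=0) / areas.sum()
    cm_mv = frame.patch_centroid["MV"]
    # orient the normal from the PVs toward the MV
    if (cm_mv - cm_pvs) @ mv_normal < 0:
        mv_normal = -mv_normal
    xi = xi_coordinate(pts, cm_pvs, cm_mv, mv_normal)

    if inside is None:
        inside = interior_mask(pts, mesh, t)
    labels = np.full(len(pts), EXTERIOR, dtype=object)
    in_laa = np.zeros(len(pts), dtype=bool)
    if mesh.ostium_point is not None:
        in_laa = ((pts - mesh.ostium_point) @ mesh.ostium_normal) > 0
        labels[inside & in_laa] = LAA
        if not np.any(inside & in_laa):
            raise ValueError("empty appendage region: ostium plane misplaced?")
    rest = inside & ~in_laa
    # vein lumens can sit slightly beyond the PV centroid (xi < 0) and the
    # mitral stub beyond its centroid (xi > 1); clip so the cut limits behave:
    # xi_cut = 0 empties LAPV, xi_cut = 1 empties LAb
    xi_c = np.clip(xi, 0.0, 1.0)
    if xi_cut >= 1.0:
        lapv = rest
    else:
        lapv = rest & (xi_c < xi_cut)
    labels[lapv] = LAPV
    labels[rest & ~lapv] = LAB
    return RegionMasks(labels=np.asarray(labels), xi=xi, mv_point=mv_point,
                       mv_normal=mv_normal, ostium_point=mesh.ostium_point,
                       ostium_normal=mesh.ostium_normal)
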