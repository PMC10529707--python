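"""Region partition: MV plane fit, the xi coordinate and interior labeling."""

import numpy as np
import pytest

from atriaflow import (CartesianGrid, enclosed_volume, fit_mv_plane, laa_volume,
                       partition, xi_coordinate)
from atriaflow.regions import interior_mask, mv_boundary_points


def test_fit_plane_exact_horizontal():
    rng = np.random.default_rng(0)
    pts = np.column_stack([rng.uniform(-1, 1, 30), rng.uniform(-1, 1, 30),
                           np.full(30, 2.0)])
    p0, n = fit_mv_plane(pts)
    assert abs(n[2]) == pytest.approx(1.0, abs=1e-12)
    assert p0[2] == pytest.approx(2.0, abs=1e-12)


def test_fit_plane_symmetric_perturbation_unchanged():
    rng = np.random.default_rng(1)
    base = np.column_stack([rng.uniform(-1, 1, 20), rng.uniform(-1, 1, 20),
                            np.zeros(20)])
    eps = np.zeros((40, 3))
    eps[:20, 2] = 1e-3
    eps[20:, 2] = -1e-3
    pts = np.vstack([base, base]) + eps
    _, n = fit_mv_plane(pts)
    assert abs(n[2]) == pytest.approx(1.0, abs=1e-9)


def test_fit_plane_matches_covariance_oracle():
    """Total least squares = smallest-eigenvalue direction of the covariance."""
    rng = np.random.default_rng(2)
    t = rng.uniform(0, 2 * np.pi, 60)
    ring = np.column_stack([2 * np.cos(t), np.sin(t), np.zeros(60)])
    rot = np.linalg.qr(rng.standard_normal((3, 3)))[0]
    pts = ring @ rot.T + np.array([0.3, -0.5, 1.2]) + rng.normal(0, 1e-3, (60, 3))
    _, n = fit_mv_plane(pts)
    w, v = np.linalg.eigh(np.cov((pts - pts.mean(0)).T))
    n_oracle = v[:, 0]
    assert abs(n @ n_oracle) == pytest.approx(1.0, abs=1e-6)


def test_collinear_points_rejected():
    pts = np.column_stack([np.arange(5.0), np.arange(5.0), np.arange(5.0)])
    with pytest.raises(ValueError, match="collinear"):
        fit_mv_plane(pts)


def test_xi_coordinate_affine():
    cm_pv = np.array([0.0, 0.0, 0.0])
    cm_mv = np.array([0.0, 0.0, 2.0])
    n = np.array([0.0, 0.0, 1.0])
    pts = np.array([[0, 0, 1.0], [0, 0, 0.0], [0, 0, 2.0], [5, -3, 0.4]])
    xi = xi_coordinate(pts, cm_pv, cm_mv, n)
    assert np.allclose(xi, [0.5, 0.0, 1.0, 0.2])


def test_xi_zero_separation_rejected():
    p = np.zeros(3)
    with pytest.raises(ValueError):
        xi_coordinate(np.zeros((1, 3)), p, np.array([1.0, 0, 0]), np.array([0, 0, 1.0]))


# ---------------------------------------------------------------------------
# partitions of the built anatomies
# ---------------------------------------------------------------------------

def _cells(mesh, n=72):
    half = 4.0 if mesh.dim == 2 else 6.0
    g = CartesianGrid((n,) * mesh.dim, 2 * half / n, (-half,) * mesh.dim)
    return g, g.cell_centers()


def test_partition_labels_cover_interior(anatomy_2d):
    mesh, *_ = anatomy_2d
    g, cells = _cells(mesh, 96)
    masks = partition(cells, mesh, 0.1)
    labels = masks.labels
    inside = labels != "exterior"
    vol_cells = inside.sum() * g.h ** 2
    vol_mesh = enclosed_volume(mesh, 0.1)
    # one boundary shell of cells of uncertainty
    perimeter = 24.0
    assert abs(vol_cells - vol_mesh) < 1.5 * perimeter * g.h
    for name in ("LAPV", "LAb", "LAA"):
        assert (labels == name).any()


def test_partition_laa_volume_consistent(anatomy_2d):
    mesh, *_ = anatomy_2d
    g, cells = _cells(mesh, 96)
    masks = partition(cells, mesh, 0.0)
    got = (masks.labels == "LAA").sum() * g.h ** 2
    assert got == pytest.approx(laa_volume(mesh, 0.0), abs=10 * g.h)


@pytest.mark.parametrize("xi_cut,empty", [(0.0, "LAPV"), (1.0, "LAb")])
def test_partition_cut_limits(anatomy_2d, xi_cut, empty):
    mesh, *_ = anatomy_2d
    g, cells = _cells(mesh)
    masks = partition(cells, mesh, 0.2, xi_cut=xi_cut)
    assert not (masks.labels == empty).any()


def test_xi_anchored_at_centroids(anatomy_2d):
    mesh, *_ = anatomy_2d
    from atriaflow.anatomy import evaluate_mesh
    frame = evaluate_mesh(mesh, 0.3)
    g, cells = _cells(mesh)
    masks = partition(cells, mesh, 0.3)
    areas = np.array([frame.patch_area[v.name] for v in mesh.veins])
    cents = np.array([frame.patch_centroid[v.name] for v in mesh.veins])
    cm_pv = (areas[:, None] * cents).sum(0) / areas.sum()
    xi_pv = xi_coordinate(cm_pv[None, :], cm_pv, frame.patch_centroid["MV"], masks.mv_normal)
    xi_mv = xi_coordinate(frame.patch_centroid["MV"][None, :], cm_pv,
                          frame.patch_centroid["MV"], masks.mv_normal)
    assert xi_pv[0] == pytest.approx(0.0, abs=1e-12)
    assert xi_mv[0] == pytest.approx(1.0, abs=1e-12)


def test_partition_rotation_invariant(anatomy_2d):
    """Rigidly rotating anatomy and sample points leaves region counts fixed."""
    from atriaflow.anatomy import LASurfaceMesh, TubeSpec
    mesh, *_ = anatomy_2d
    ang = 0.7
    R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])

    def rot_spec(s):
        return None if s is None else TubeSpec(s.name, s.kind, tuple(R @ s.d),
                                               s.radius, s.length, s.side)

    rotated = LASurfaceMesh(
        coeffs=np.einsum("ab,nbk->nak", R, mesh.coeffs), faces=mesh.faces,
        patch_labels=mesh.patch_labels, period=mesh.period,
        veins=tuple(rot_spec(v) for v in mesh.veins), mv=rot_spec(mesh.mv),
        laa=rot_spec(mesh.laa), ostium_point=R @ mesh.ostium_point,
        ostium_normal=R @ mesh.ostium_normal)
    g, cells = _cells(mesh, 64)
    m1 = partition(cells, mesh, 0.15)
    m2 = partition(cells @ R.T, rotated, 0.15)
    for name in ("LAPV", "LAb", "LAA", "exterior"):
        n1 = (m1.labels == name).sum()
        n2 = (m2.labels == name).sum()
        assert abs(n1 - n2) <= 0.02 * max(n1, 1)


def test_partition_3d_sac_membership(anatomy_3d):
    """Cells beyond the ostium plane inside the sac are labeled LAA and their
    count matches the sac volume within a boundary shell."""
    mesh, *_ = anatomy_3d
    n = 48
    g = CartesianGrid((n,) * 3, 12.0 / n, (-6.0,) * 3)
    cells = g.cell_centers()
    masks = partition(cells, mesh, 0.0)
    vol = (masks.labels == "LAA").sum() * g.h ** 3
    sac = laa_volume(mesh, 0.0)
    # sac surface area ~ 20 cm^2 -> one shell of cells tolerance
    assert abs(vol - sac) < 25.0 * g.h


def test_interior_mask_matches_volume(anatomy_3d):
    mesh, *_ = anatomy_3d
    n = 40
    g = CartesianGrid((n,) * 3, 12.0 / n, (-6.0,) * 3)
    inside = interior_mask(g.cell_centers(), mesh, 0.0)
    vol = inside.sum() * g.h ** 3
    assert vol == pytest.approx(enclosed_volume(mesh, 0.0), rel=0.12)


def test_mean_mv_plane_option(anatomy_2d):
    mesh, *_ = anatomy_2d
    g, cells = _cells(mesh, 48)
    m_inst = partition(cells, mesh, 0.2, use_mean_mv_plane=False)
    m_mean = partition(cells, mesh, 0.2, use_mean_mv_plane=True)
    assert abs(m_inst.mv_normal @ m_mean.mv_normal) > 0.999
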