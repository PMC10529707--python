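"""Synthetic anatomy: Fourier fits, enclosed volumes, patch geometry, motion."""

import numpy as np
import pytest
import trimesh

from atriaflow import (enclosed_volume, evaluate_mesh, fourier_eval, fourier_fit,
                       laa_volume, make_idealized_la, normal_anatomy_config,
                       volume_rate)
from atriaflow.anatomy import LASurfaceMesh, ostium_ring


# ---------------------------------------------------------------------------
# fourier_fit
# ---------------------------------------------------------------------------

def test_fourier_fit_pure_harmonic():
    t = np.linspace(0, 1, 10, endpoint=False)
    frames = np.cos(2 * np.pi * t)[:, None]
    coeffs, resid = fourier_fit(frames, K=1, period=1.0)
    assert resid < 1e-12
    assert coeffs[0] == pytest.approx([0.0, 1.0, 0.0], abs=1e-12)


def test_fourier_fit_constant():
    frames = np.full((7, 3), 2.5)
    coeffs, resid = fourier_fit(frames, K=2, period=1.0)
    assert resid < 1e-12
    assert np.allclose(coeffs[..., 0], 2.5)
    assert np.abs(coeffs[..., 1:]).max() < 1e-12


def test_fourier_fit_band_limited_exact_off_sample():
    """A 3-harmonic signal fitted with K=3 reproduces the signal anywhere."""
    rng = np.random.default_rng(0)
    a = rng.normal(size=7)  # a0, a1..a3, b1..b3

    def signal(t):
        out = a[0] * np.ones_like(t)
        for k in range(1, 4):
            out += a[k] * np.cos(2 * np.pi * k * t) + a[3 + k] * np.sin(2 * np.pi * k * t)
        return out

    t = np.linspace(0, 1, 16, endpoint=False)
    coeffs, resid = fourier_fit(signal(t)[:, None], K=3, period=1.0)
    assert resid < 1e-12
    for t_off in (0.123, 0.456, 0.789):
        got = fourier_eval(coeffs, t_off, 1.0)[0]
        assert got == pytest.approx(signal(np.array([t_off]))[0], abs=1e-10)


def test_fourier_fit_underdetermined_raises():
    with pytest.raises(ValueError, match="underdetermined"):
        fourier_fit(np.zeros((6, 1)), K=3, period=1.0)


# ---------------------------------------------------------------------------
# enclosed_volume
# ---------------------------------------------------------------------------

def _static_mesh(vertices, faces):
    coeffs = np.zeros(vertices.shape + (3,))
    coeffs[..., 0] = vertices
    labels = np.full(len(faces), "wall", dtype=object)
    return LASurfaceMesh(coeffs=coeffs, faces=np.asarray(faces), patch_labels=labels,
                         period=1.0, veins=(), mv=None, laa=None,
                         ostium_point=None, ostium_normal=None)


@pytest.mark.parametrize("scale", [1.0, 0.5, 2.0])
def test_enclosed_volume_sphere_scaling(scale):
    ico = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
    mesh = _static_mesh(np.asarray(ico.vertices) * scale, np.asarray(ico.faces))
    expected = 4.0 / 3.0 * np.pi * scale ** 3
    assert enclosed_volume(mesh, 0.0) == pytest.approx(expected, rel=5e-3)


def test_enclosed_volume_cube_exact():
    box = trimesh.creation.box(extents=(2.0, 2.0, 2.0))
    mesh = _static_mesh(np.asarray(box.vertices), np.asarray(box.faces))
    assert enclosed_volume(mesh, 0.0) == pytest.approx(8.0, abs=1e-12)


def test_enclosed_volume_orientation_independent():
    box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    faces = np.asarray(box.faces)[:, ::-1]  # flipped orientation
    mesh = _static_mesh(np.asarray(box.vertices), faces)
    assert enclosed_volume(mesh, 0.0) == pytest.approx(1.0, abs=1e-12)


def test_open_mesh_rejected():
    ico = trimesh.creation.icosphere(subdivisions=2)
    mesh = _static_mesh(np.asarray(ico.vertices), np.asarray(ico.faces)[:-1])
    with pytest.raises(ValueError, match="boundary edges"):
        enclosed_volume(mesh, 0.0)


# ---------------------------------------------------------------------------
# built anatomies
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("fixture", ["anatomy_2d", "anatomy_3d"])
def test_volume_markers_within_two_percent(fixture, request):
    mesh, la_wf, lv_wf, laa_wf, cfg = request.getfixturevalue(fixture)
    for key, target in (("t_min", cfg.v_min), ("t_max", cfg.v_max),
                        ("t_pre_a", cfg.v_pre_a)):
        tk = la_wf.markers[key]
        got = enclosed_volume(mesh, tk) - laa_volume(mesh, tk)
        assert got == pytest.approx(target, rel=0.02)


@pytest.mark.parametrize("fixture", ["anatomy_2d", "anatomy_3d"])
def test_mesh_is_closed_and_periodic(fixture, request):
    mesh, *_ = request.getfixturevalue(fixture)
    mesh.check_closed()
    assert np.allclose(mesh.positions(0.2), mesh.positions(0.2 + mesh.period), atol=1e-12)
    f1 = evaluate_mesh(mesh, 0.35)
    f2 = evaluate_mesh(mesh, 0.35 + mesh.period)
    for k in f1.patch_area:
        assert f1.patch_area[k] == pytest.approx(f2.patch_area[k], abs=1e-12)


def test_build_is_deterministic():
    cfg = normal_anatomy_config(dim=2, seed=7)
    m1, *_ = make_idealized_la(cfg)
    m2, *_ = make_idealized_la(normal_anatomy_config(dim=2, seed=7))
    assert np.array_equal(m1.coeffs, m2.coeffs)
    assert np.array_equal(m1.faces, m2.faces)


def test_different_seed_different_shape():
    m1, *_ = make_idealized_la(normal_anatomy_config(dim=2, seed=7))
    m2, *_ = make_idealized_la(normal_anatomy_config(dim=2, seed=8))
    assert not np.allclose(m1.coeffs, m2.coeffs)


@pytest.mark.parametrize("fixture", ["anatomy_2d", "anatomy_3d"])
def test_caps_planar_and_normals_oriented(fixture, request):
    mesh, *_ = request.getfixturevalue(fixture)
    for t in (0.0, 0.37, 0.81):
        x = mesh.positions(t)
        frame = evaluate_mesh(mesh, t)
        for spec in list(mesh.veins) + [mesh.mv]:
            verts = np.unique(mesh.patch_faces(spec.name).ravel())
            dev = np.abs(x[verts] @ spec.d - spec.length)
            assert dev.max() < 2e-3  # stated cap-planarity tolerance, cm
            n = frame.patch_normal[spec.name]
            assert np.linalg.norm(n) == pytest.approx(1.0, abs=1e-12)
            # PV normals point into the chamber, the MV normal out of it
            inward = -spec.d if spec.kind == "pv" else spec.d
            assert n @ inward > 0.99
            assert frame.patch_area[spec.name] > 0


def test_cap_area_close_to_disc_area(anatomy_2d):
    mesh, *_ = anatomy_2d
    frame = evaluate_mesh(mesh, 0.0)
    for v in mesh.veins:
        assert frame.patch_area[v.name] == pytest.approx(2 * v.radius, rel=0.12)


def test_volume_rate_matches_finite_difference(anatomy_2d):
    mesh, *_ = anatomy_2d
    eps = 1e-6
    for t in (0.1, 0.33, 0.52, 0.9):
        fd = (enclosed_volume(mesh, t + eps) - enclosed_volume(mesh, t - eps)) / (2 * eps)
        assert volume_rate(mesh, t) == pytest.approx(fd, rel=1e-5, abs=1e-5)


def test_zeroed_harmonics_give_static_chamber(anatomy_2d):
    mesh, *_ = anatomy_2d
    frozen = LASurfaceMesh(coeffs=mesh.coeffs.copy(), faces=mesh.faces,
                           patch_labels=mesh.patch_labels, period=mesh.period,
                           veins=mesh.veins, mv=mesh.mv, laa=mesh.laa,
                           ostium_point=mesh.ostium_point,
                           ostium_normal=mesh.ostium_normal)
    frozen.coeffs[..., 1:] = 0.0
    assert volume_rate(frozen, 0.3) == pytest.approx(0.0, abs=1e-12)
    assert enclosed_volume(frozen, 0.1) == pytest.approx(enclosed_volume(frozen, 0.7))


def test_laa_volume_tracks_targets(anatomy_2d):
    mesh, la_wf, lv_wf, laa_wf, cfg = anatomy_2d
    assert laa_volume(mesh, laa_wf.markers["t_min"]) == pytest.approx(cfg.laa_v_min, rel=0.03)
    assert laa_volume(mesh, laa_wf.markers["t_max"]) == pytest.approx(cfg.laa_v_max, rel=0.03)


def test_ostium_ring_lies_on_plane(anatomy_3d):
    mesh, *_ = anatomy_3d
    pts = ostium_ring(mesh, 0.25)
    assert len(pts) > 10
    assert np.abs((pts - mesh.ostium_point) @ mesh.ostium_normal).max() < 1e-9


def test_infeasible_configs_rejected():
    with pytest.raises(ValueError):
        make_idealized_la(normal_anatomy_config(dim=2, v_min=50.0, v_max=40.0, v_pre_a=45.0))
    cfg = normal_anatomy_config(dim=2)
    cfg.laa_v_max = 40.0  # appendage larger than the chamber can host
    with pytest.raises(ValueError, match="appendage"):
        make_idealized_la(cfg)
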