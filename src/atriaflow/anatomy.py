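"""Idealized, time-periodic left-atrial geometries with labeled patches.

The anatomy stands in for a registered 4D-CT surface segmentation: a closed
triangulated (3D) or polygonal (2D) surface with labeled patches (wall, the
pulmonary-vein inlet caps, the mitral orifice, and the appendage ostium ring)
whose vertex trajectories are stored as truncated temporal Fourier series over
one heartbeat.

Construction uses a star-shaped radial support function: the chamber is an
ellipsoid (with a smooth seeded shape perturbation), each pulmonary vein and
the mitral orifice is a radially oriented cylindrical stub ending in an
exactly planar cap, and the appendage is a radially oriented capsule (cylinder
with spherical tip).  The surface is the pointwise maximum of these supports
along each sampling direction, which is automatically watertight.  Wall motion
scales the chamber (and appendage) supports by time-dependent factors found by
1D root-finding so that the enclosed volumes track prescribed volume
waveforms; the per-vertex trajectories are then least-squares projected onto K
temporal harmonics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .waveforms import (VolumeWaveform, band_limited, la_volume_waveform,
                        laa_volume_waveform, lv_volume_waveform)

__all__ = [
    "TubeSpec",
    "AnatomyConfig",
    "LASurfaceMesh",
    "MeshFrame",
    "fourier_fit",
    "fourier_eval",
    "enclosed_volume",
    "volume_rate",
    "evaluate_mesh",
    "make_idealized_la",
    "normal_anatomy_config",
    "impaired_anatomy_config",
]

WALL = "wall"
LAA_OSTIUM_RING = "LAA_ostium_ring"
MV = "MV"


# ---------------------------------------------------------------------------
# Fourier temporal series
# ---------------------------------------------------------------------------

def _design_matrix(t: np.ndarray, K: int, period: float) -> np.ndarray:
    w = 2.0 * np.pi / period
    cols = [np.ones_like(t)]
    for k in range(1, K + 1):
        cols.append(np.cos(k * w * t))
        cols.append(np.sin(k * w * t))
    return np.stack(cols, axis=1)  # (M, 2K+1)


def fourier_fit(frames: np.ndarray, K: int, period: float,
                times: np.ndarray | None = None):
    """Least-squares fit of truncated Fourier series to sampled trajectories.

    Parameters
    ----------
    frames : (M, ...) array of values at M time samples (regular over one
        period if ``times`` is omitted).
    K : number of harmonics; requires M > 2K.

    Returns ``(coeffs, residual)`` where ``coeffs`` has shape ``(..., 2K+1)``
    ordered ``[a0, a1, b1, ..., aK, bK]`` and ``residual`` is the RMS misfit
    at the sample times.
    """
    frames = np.asarray(frames, dtype=float)
    M = frames.shape[0]
    if K < 1:
        raise ValueError("K must be >= 1")
    if M <= 2 * K:
        raise ValueError(f"underdetermined Fourier fit: need M > 2K samples (M={M}, K={K})")
    if times is None:
        times = np.linspace(0.0, period, M, endpoint=False)
    A = _design_matrix(np.asarray(times, dtype=float), K, period)
    rhs = frames.reshape(M, -1)
    coeffs, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    resid = A @ coeffs - rhs
    residual = float(np.sqrt(np.mean(resid ** 2)))
    out = coeffs.T.reshape(frames.shape[1:] + (2 * K + 1,))
    return out, residual


def fourier_eval(coeffs: np.ndarray, t: float, period: float, derivative: int = 0) -> np.ndarray:
    """Evaluate Fourier series (or its time derivative) at scalar time t."""
    K = (coeffs.shape[-1] - 1) // 2
    w = 2.0 * np.pi / period
    kw = w * np.arange(1, K + 1)
    th = kw * t
    basis = np.empty(2 * K + 1)
    if derivative == 0:
        basis[0] = 1.0
        basis[1::2] = np.cos(th)
        basis[2::2] = np.sin(th)
    elif derivative == 1:
        basis[0] = 0.0
        basis[1::2] = -kw * np.sin(th)
        basis[2::2] = kw * np.cos(th)
    else:
        raise ValueError("only derivative orders 0 and 1 are supported")
    return coeffs @ basis


def fourier_eval_pair(coeffs: np.ndarray, t: float, period: float):
    """Positions and velocities in one pass (shared trigonometric basis)."""
    K = (coeffs.shape[-1] - 1) // 2
    w = 2.0 * np.pi / period
    kw = w * np.arange(1, K + 1)
    c = np.cos(kw * t)
    s = np.sin(kw * t)
    b0 = np.empty(2 * K + 1)
    b1 = np.empty(2 * K + 1)
    b0[0] = 1.0
    b0[1::2] = c
    b0[2::2] = s
    b1[0] = 0.0
    b1[1::2] = -kw * s
    b1[2::2] = kw * c
    return coeffs @ b0, coeffs @ b1


# ---------------------------------------------------------------------------
# Geometry supports
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TubeSpec:
    """A radially oriented feature attached to the chamber.

    ``kind`` is one of ``"pv"`` (open planar inlet cap), ``"mv"`` (planar
    orifice cap) or ``"laa"`` (closed capsule sac).  ``direction`` is the unit
    outward axis, ``radius`` the cross-section radius (cm; half-width in 2D)
    and ``length`` the distance from the chamber centroid to the cap plane
    (capsule tip center for the appendage).
    """

    name: str
    kind: str
    direction: tuple
    radius: float
    length: float
    side: str | None = None  # "R" / "L" for pulmonary veins

    @property
    def d(self) -> np.ndarray:
        d = np.asarray(self.direction, dtype=float)
        return d / np.linalg.norm(d)


def _tube_support(dirs: np.ndarray, spec: TubeSpec, radius_scale: float = 1.0,
                  length_scale: float = 1.0) -> np.ndarray:
    """Radial extent of a tube/capsule support along each unit direction."""
    r = spec.radius * radius_scale
    L = spec.length * length_scale
    cosp = dirs @ spec.d
    sinp = np.sqrt(np.clip(1.0 - cosp ** 2, 0.0, None))
    out = np.zeros(len(dirs))
    if spec.kind in ("pv", "mv"):
        # flat cap at x.d = L  union  cylinder wall of radius r
        with np.errstate(divide="ignore"):
            cap = np.where(cosp > 0, L / np.maximum(cosp, 1e-12), 0.0)
            wall = np.where(sinp > 0, r / np.maximum(sinp, 1e-12), np.inf)
        out = np.where(cosp > 0, np.minimum(cap, wall), 0.0)
    elif spec.kind == "laa":
        # capsule: cylinder along d up to L, spherical tip of radius r at L*d
        with np.errstate(divide="ignore"):
            wall = np.where(sinp > 0, r / np.maximum(sinp, 1e-12), 0.0)
        wall_ok = (cosp > 0) & (wall * cosp <= L)
        disc = (L * cosp) ** 2 - (L ** 2 - r ** 2)
        sph_ok = disc >= 0.0
        sph = np.where(sph_ok, L * cosp + np.sqrt(np.clip(disc, 0.0, None)), 0.0)
        out = np.maximum(np.where(wall_ok, wall, 0.0), np.where(sph_ok, sph, 0.0))
    else:  # pragma: no cover
        raise ValueError(f"unknown tube kind {spec.kind!r}")
    return out


class _ChamberSupport:
    """Seeded smooth ellipsoidal chamber support."""

    def __init__(self, radii: np.ndarray, bump_dirs: np.ndarray, bump_amps: np.ndarray):
        self.radii = np.asarray(radii, dtype=float)
        self.bump_dirs = bump_dirs
        self.bump_amps = bump_amps

    def __call__(self, dirs: np.ndarray, scale: float) -> np.ndarray:
        q = np.sqrt(np.sum((dirs / self.radii) ** 2, axis=1))
        base = 1.0 / q
        dim = dirs.shape[1]
        pert = np.ones(len(dirs))
        for u, eps in zip(self.bump_dirs, self.bump_amps):
            pert += eps * ((dirs @ u) ** 2 - 1.0 / dim)
        return scale * base * pert


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class AnatomyConfig:
    """Parameters of the idealized atrium and its prescribed function.

    Volumes in ml (cm^3) for 3D, chamber areas in cm^2 for the planar (2D)
    analogue; lengths in cm, times in s.
    """

    dim: int = 3
    chamber_radii: tuple = (1.0, 0.85, 0.75)  # relative ellipsoid axes
    veins: tuple = ()
    mv: TubeSpec | None = None
    laa: TubeSpec | None = None
    # volume waveform targets
    v_min: float = 59.6
    v_max: float = 108.0
    v_pre_a: float = 94.3
    lvsv: float = 72.2
    lv_edv: float = 160.0
    e_fraction: float = 0.65
    laa_v_min: float = 4.32
    laa_v_max: float = 8.97
    period: float = 1.0  # heart rate 60 min^-1
    # discretization
    harmonics: int = 8
    n_time: int = 32
    n_theta: int = 2880         # 2D boundary sampling; must resolve the
                                # near-radial tube side walls (arc steps there
                                # are ~20x the nominal boundary spacing)
    subdivisions: int = 5       # 3D icosphere subdivision level
    bump_amplitude: float = 0.02
    ostium_margin: float = 0.12  # cm beyond max chamber extent along LAA axis
    blend: float = 0.08          # junction fillet length scale, cm
    seed: int = 0

    def validate(self):
        if not (0.0 < self.v_min < self.v_pre_a < self.v_max):
            raise ValueError("volume markers must satisfy 0 < V_min < V_preA < V_max")
        if self.lvsv <= 0:
            raise ValueError("LVSV must be positive")
        if self.harmonics < 1:
            raise ValueError("need at least one harmonic")
        if self.n_time <= 2 * self.harmonics:
            raise ValueError("n_time must exceed twice the harmonic count")
        if self.dim not in (2, 3):
            raise ValueError("dim must be 2 or 3")
        specs = list(self.veins) + [s for s in (self.mv, self.laa) if s is not None]
        for a in range(len(specs)):
            for b in range(a + 1, len(specs)):
                sa, sb = specs[a], specs[b]
                gap = np.arccos(np.clip(sa.d @ sb.d, -1, 1))
                need = np.arctan2(sa.radius, sa.length * 0.5) + np.arctan2(sb.radius, sb.length * 0.5)
                if gap < need:
                    raise ValueError(f"features {sa.name!r} and {sb.name!r} overlap "
                                     f"(angular gap {np.degrees(gap):.1f} deg)")


def normal_anatomy_config(dim: int = 2, seed: int = 0, **overrides) -> AnatomyConfig:
    """Default study anatomy with normal atrial function.

    The 3D variant targets the volumes of a normal subject (V_min 59.6,
    V_max 108, V_preA 94.3 ml, LVSV 72.2 ml, LAA 4.32-8.97 ml, 60 bpm).  The
    planar variant is a scaled analogue with cross-sectional areas in cm^2
    chosen to preserve the ejection-fraction profile (global EF 0.40,
    booster-dominated emptying, LAA EF 0.53) and physiological velocities.
    """
    if dim == 3:
        cfg = AnatomyConfig(
            dim=3,
            chamber_radii=(1.0, 0.85, 0.75),
            veins=(
                TubeSpec("PV_RS", "pv", (0.62, 0.42, 0.66), 0.62, 4.3, side="R"),
                TubeSpec("PV_RI", "pv", (0.80, -0.25, 0.54), 0.55, 4.3, side="R"),
                TubeSpec("PV_LS", "pv", (-0.45, 0.52, 0.73), 0.66, 4.3, side="L"),
                TubeSpec("PV_LI", "pv", (-0.74, -0.05, 0.67), 0.60, 4.3, side="L"),
            ),
            mv=TubeSpec("MV", "mv", (0.0, 0.0, -1.0), 1.15, 3.0),
            laa=TubeSpec("LAA", "laa", (-0.85, -0.42, -0.15), 1.35, 3.9),
            seed=seed,
        )
    else:
        cfg = AnatomyConfig(
            dim=2,
            chamber_radii=(1.0, 0.92),
            veins=(
                TubeSpec("PV_R", "pv", (np.cos(np.radians(60)), np.sin(np.radians(60))), 0.315, 3.3, side="R"),
                TubeSpec("PV_L", "pv", (np.cos(np.radians(120)), np.sin(np.radians(120))), 0.385, 3.3, side="L"),
            ),
            mv=TubeSpec("MV", "mv", (0.0, -1.0), 0.75, 2.60),
            laa=TubeSpec("LAA", "laa", (np.cos(np.radians(205)), np.sin(np.radians(205))), 0.55, 2.9),
            v_min=9.6, v_max=14.4, v_pre_a=13.0, lvsv=8.0, lv_edv=20.0,
            laa_v_min=0.61, laa_v_max=1.30,
            seed=seed,
        )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def impaired_anatomy_config(dim: int = 2, seed: int = 0, **overrides) -> AnatomyConfig:
    """AF-like variant: enlarged chamber, reduced global EF, near-zero booster
    contribution, monophasic mitral filling and low LAA emptying fraction."""
    cfg = normal_anatomy_config(dim=dim, seed=seed)
    if dim == 3:
        cfg.v_min, cfg.v_max, cfg.v_pre_a = 119.0, 155.0, 149.0
        cfg.lvsv, cfg.lv_edv = 66.7, 150.0
        cfg.laa_v_min, cfg.laa_v_max = 9.10, 11.6
    else:
        cfg.v_min, cfg.v_max, cfg.v_pre_a = 12.4, 15.3, 13.3
        cfg.lvsv, cfg.lv_edv = 7.0, 18.0
        cfg.laa_v_min, cfg.laa_v_max = 1.02, 1.30
    cfg.e_fraction = 1.0  # no atrial kick
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


# ---------------------------------------------------------------------------
# Mesh container
# ---------------------------------------------------------------------------

@dataclass
class LASurfaceMesh:
    """Closed labeled surface with Fourier vertex trajectories.

    ``coeffs`` has shape (n_vertices, dim, 2K+1); ``faces`` is (n_faces, 2)
    segment connectivity in 2D or (n_faces, 3) triangles in 3D;
    ``patch_labels`` holds one string per face.
    """

    coeffs: np.ndarray
    faces: np.ndarray
    patch_labels: np.ndarray
    period: float
    veins: tuple
    mv: TubeSpec | None
    laa: TubeSpec | None
    ostium_point: np.ndarray | None
    ostium_normal: np.ndarray | None
    fit_residual: float = 0.0

    @property
    def dim(self) -> int:
        return self.coeffs.shape[1]

    @property
    def n_vertices(self) -> int:
        return self.coeffs.shape[0]

    def positions(self, t: float) -> np.ndarray:
        return fourier_eval(self.coeffs, t, self.period)

    def velocities(self, t: float) -> np.ndarray:
        return fourier_eval(self.coeffs, t, self.period, derivative=1)

    def patch_faces(self, name: str) -> np.ndarray:
        return self.faces[self.patch_labels == name]

    def check_closed(self, t: float = 0.0):
        """Raise if the surface has boundary edges (open mesh)."""
        if self.dim == 2:
            counts = np.zeros(self.n_vertices, dtype=int)
            np.add.at(counts, self.faces.ravel(), 1)
            n_open = int(np.sum(counts != 2))
        else:
            edges = np.sort(np.concatenate([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                                            self.faces[:, [2, 0]]]), axis=1)
            _, cnt = np.unique(edges, axis=0, return_counts=True)
            n_open = int(np.sum(cnt != 2))
        if n_open:
            raise ValueError(f"surface is not closed: {n_open} boundary edges")


@dataclass
class MeshFrame:
    """Instantaneous mesh evaluation: positions plus per-patch planar-cap
    geometry (area, inward/outward unit normal, centroid)."""

    t: float
    positions: np.ndarray
    patch_area: dict
    patch_normal: dict
    patch_centroid: dict


# ---------------------------------------------------------------------------
# Volume computations
# ---------------------------------------------------------------------------

def _cross2(a: np.ndarray, b: np.ndarray):
    return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]


def _signed_volume(positions: np.ndarray, faces: np.ndarray) -> float:
    if positions.shape[1] == 2:
        a = positions[faces[:, 0]]
        b = positions[faces[:, 1]]
        return 0.5 * float(np.sum(_cross2(a, b)))
    a = positions[faces[:, 0]]
    b = positions[faces[:, 1]]
    c = positions[faces[:, 2]]
    return float(np.sum(np.einsum("ij,ij->i", a, np.cross(b, c)))) / 6.0


def enclosed_volume(mesh: LASurfaceMesh, t: float) -> float:
    """Orientation-independent enclosed volume (cm^3; area in cm^2 for 2D)."""
    mesh.check_closed(t)
    return abs(_signed_volume(mesh.positions(t), mesh.faces))


def volume_rate(mesh: LASurfaceMesh, t: float) -> float:
    """Exact d/dt of the enclosed volume from the Fourier vertex velocities."""
    x = mesh.positions(t)
    v = mesh.velocities(t)
    f = mesh.faces
    if mesh.dim == 2:
        rate = 0.5 * float(np.sum(_cross2(v[f[:, 0]], x[f[:, 1]]) + _cross2(x[f[:, 0]], v[f[:, 1]])))
    else:
        a, b, c = x[f[:, 0]], x[f[:, 1]], x[f[:, 2]]
        da, db, dc = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
        rate = (np.sum(np.einsum("ij,ij->i", da, np.cross(b, c)))
                + np.sum(np.einsum("ij,ij->i", a, np.cross(db, c)))
                + np.sum(np.einsum("ij,ij->i", a, np.cross(b, dc)))) / 6.0
    sign = getattr(mesh, "_orient_sign", None)
    if sign is None:
        # face orientation does not change over the cycle; compute once
        sign = 1.0 if _signed_volume(x, f) >= 0 else -1.0
        mesh._orient_sign = sign
    return sign * float(rate)


def _face_measure_normal(positions: np.ndarray, faces: np.ndarray):
    """Per-face measure (length/area) and outward-agnostic unit normal."""
    if positions.shape[1] == 2:
        e = positions[faces[:, 1]] - positions[faces[:, 0]]
        meas = np.linalg.norm(e, axis=1)
        n = np.stack([e[:, 1], -e[:, 0]], axis=1) / np.maximum(meas, 1e-300)[:, None]
        return meas, n
    cr = np.cross(positions[faces[:, 1]] - positions[faces[:, 0]],
                  positions[faces[:, 2]] - positions[faces[:, 0]])
    meas = 0.5 * np.linalg.norm(cr, axis=1)
    n = cr / np.maximum(2.0 * meas, 1e-300)[:, None]
    return meas, n


def evaluate_mesh(mesh: LASurfaceMesh, t: float) -> MeshFrame:
    """Vertex positions plus instantaneous area A_i, unit normal and centroid
    of every planar cap patch (PV inlets and the mitral orifice).

    PV cap normals point into the chamber; the MV normal points out of it.
    """
    x = mesh.positions(t)
    areas, normals, centroids = {}, {}, {}
    for spec in list(mesh.veins) + ([mesh.mv] if mesh.mv is not None else []):
        f = mesh.patch_faces(spec.name)
        if len(f) == 0:
            raise ValueError(f"patch {spec.name!r} has no faces")
        meas, _ = _face_measure_normal(x, f)
        area = float(np.sum(meas))
        if area <= 0:
            raise ValueError(f"degenerate (zero-area) patch {spec.name!r}")
        w = meas / area
        cent = np.einsum("f,fd->d", w, x[f].mean(axis=1))
        n = spec.d if spec.kind == "mv" else -spec.d  # in for PVs, out for MV
        areas[spec.name], normals[spec.name], centroids[spec.name] = area, n, cent
    return MeshFrame(t=t, positions=x, patch_area=areas, patch_normal=normals,
                     patch_centroid=centroids)


def ostium_ring(mesh: LASurfaceMesh, t: float) -> np.ndarray:
    """Points where surface edges cross the appendage ostium plane."""
    if mesh.ostium_point is None:
        raise ValueError("anatomy has no appendage ostium plane")
    x = mesh.positions(t)
    p0, n = mesh.ostium_point, mesh.ostium_normal
    f = mesh.faces
    pts = []
    sd = (x - p0) @ n
    edges = [(0, 1)] if mesh.dim == 2 else [(0, 1), (1, 2), (2, 0)]
    for i, j in edges:
        a, b = sd[f[:, i]], sd[f[:, j]]
        cross = (a * b) < 0
        if np.any(cross):
            lam = a[cross] / (a[cross] - b[cross])
            pts.append(x[f[cross, i]] + lam[:, None] * (x[f[cross, j]] - x[f[cross, i]]))
    if not pts:
        raise ValueError("ostium plane does not intersect the surface")
    return np.unique(np.round(np.concatenate(pts), 12), axis=0)


# ---------------------------------------------------------------------------
# Builder
# ---------------------------------------------------------------------------

def _sampling(config: AnatomyConfig):
    """Unit sampling directions and face connectivity."""
    if config.dim == 2:
        theta = np.linspace(0.0, 2.0 * np.pi, config.n_theta, endpoint=False)
        dirs = np.stack([np.cos(theta), np.sin(theta)], axis=1)
        idx = np.arange(config.n_theta)
        faces = np.stack([idx, (idx + 1) % config.n_theta], axis=1)
        return dirs, faces
    import trimesh
    ico = trimesh.creation.icosphere(subdivisions=config.subdivisions, radius=1.0)
    dirs = np.asarray(ico.vertices, dtype=float)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return dirs, np.asarray(ico.faces, dtype=int)


def _make_chamber(config: AnatomyConfig, rng: np.random.Generator) -> _ChamberSupport:
    dim = config.dim
    n_bumps = 4
    bump_dirs = rng.normal(size=(n_bumps, dim))
    bump_dirs /= np.linalg.norm(bump_dirs, axis=1, keepdims=True)
    bump_amps = rng.normal(0.0, config.bump_amplitude, size=n_bumps)
    return _ChamberSupport(np.asarray(config.chamber_radii), bump_dirs, bump_amps)


def _radial(dirs, chamber, specs, s_ch, s_laa, blend: float = 0.08):
    """Union of the feature supports.

    A soft maximum (log-sum-exp with length scale ``blend``, cm) fillets the
    junctions between the moving chamber and the static stubs so that vertex
    trajectories are smooth in time and their truncated Fourier fits do not
    ring; ``blend = 0`` recovers the hard union.  Cap planes are far enough
    from the chamber that their planarity deviation stays below ~1e-3 cm.
    """
    vals = [chamber(dirs, s_ch)]
    for spec in specs:
        if spec.kind == "laa":
            vals.append(_tube_support(dirs, spec, radius_scale=s_laa, length_scale=1.0))
        else:
            vals.append(_tube_support(dirs, spec))
    V = np.stack(vals)
    m = V.max(axis=0)
    if blend <= 0.0:
        return m
    return m + blend * np.log(np.sum(np.exp((V - m) / blend), axis=0))


def _volume_of_radial(dirs, faces, R, dim):
    pos = R[:, None] * dirs
    if dim == 2:
        return abs(0.5 * np.sum(_cross2(pos[faces[:, 0]], pos[faces[:, 1]])))
    a, b, c = pos[faces[:, 0]], pos[faces[:, 1]], pos[faces[:, 2]]
    return abs(np.sum(np.einsum("ij,ij->i", a, np.cross(b, c)))) / 6.0


def make_idealized_la(config: AnatomyConfig):
    """Build the idealized moving anatomy and its driving waveforms.

    Returns ``(mesh, la_waveform, lv_waveform, laa_waveform)``.  The LA
    waveform describes the chamber body (appendage excluded, as in the
    functional indices); the mesh's total enclosed volume additionally carries
    the appendage contribution.  The enclosed body volume at the marker times
    matches the requested V_min / V_max / V_preA within 2%.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    dirs, faces = _sampling(config)
    chamber = _make_chamber(config, rng)
    specs_all = list(config.veins) + [s for s in (config.mv, config.laa) if s is not None]
    specs_body = [s for s in specs_all if s.kind != "laa"]

    # chamber targets are band-limited to the mesh's K harmonics so the wall
    # motion can represent them without ringing in dV/dt (and hence in Q_PV);
    # the LV waveform stays in closed lobe form (its rate sign defines the
    # valve state and is never realized by a mesh)
    la_wf = band_limited(la_volume_waveform(config.v_min, config.v_max,
                                            config.v_pre_a, config.period),
                         config.harmonics)
    lv_wf = lv_volume_waveform(config.lv_edv, config.lvsv, config.e_fraction, config.period)
    laa_wf = None
    if config.laa is not None:
        laa_wf = band_limited(laa_volume_waveform(config.laa_v_min, config.laa_v_max,
                                                  config.period), config.harmonics)

    # normalize chamber scale: find s0 with body volume = v_min as bracket aid
    def body_vol(s):
        return _volume_of_radial(dirs, faces,
                                 _radial(dirs, chamber, specs_body, s, 1.0, config.blend), config.dim)

    def total_vol(s_ch, s_laa):
        return _volume_of_radial(dirs, faces,
                                 _radial(dirs, chamber, specs_all, s_ch, s_laa, config.blend), config.dim)

    times = np.linspace(0.0, config.period, config.n_time, endpoint=False)
    frames = np.empty((config.n_time, len(dirs), config.dim))
    s_lo, s_hi = 0.2, 8.0
    if not (body_vol(s_lo) < config.v_min and body_vol(s_hi) > config.v_max):
        raise ValueError("chamber radii cannot bracket the requested volumes; "
                         "adjust chamber_radii or the volume targets")

    # the appendage ostium plane is static, just beyond the chamber extent
    # along the sac axis at maximal dilation
    ostium_point = ostium_normal = None
    if config.laa is not None:
        d = config.laa.d
        s_at_vmax = brentq(lambda s: body_vol(s) - config.v_max, s_lo, s_hi, xtol=1e-8)
        along = chamber(d[None, :], s_at_vmax)[0]
        ostium_point = (along + config.ostium_margin) * d
        ostium_normal = d

        def sac_beyond(s_laa):
            R = _radial(dirs, chamber, specs_all, s_at_vmax, s_laa, config.blend)
            return _volume_beyond_plane(R[:, None] * dirs, faces, ostium_point, ostium_normal)

        if sac_beyond(0.05) > config.laa_v_min or sac_beyond(1.8) < config.laa_v_max:
            raise ValueError("appendage cannot bracket the requested LAA volumes; "
                             "it may be too large or buried in the chamber")

    for k, tk in enumerate(times):
        s_laa, sac_v = 1.0, 0.0
        if config.laa is not None:
            sac_v = laa_wf.volume(tk)
            s_laa = brentq(lambda s: sac_beyond(s) - sac_v, 0.05, 1.8, xtol=1e-10)
        s_ch = brentq(lambda s: total_vol(s, s_laa) - sac_v - la_wf.volume(tk),
                      s_lo, s_hi, xtol=1e-10)
        R = _radial(dirs, chamber, specs_all, s_ch, s_laa, config.blend)
        frames[k] = R[:, None] * dirs

    coeffs, residual = fourier_fit(frames, config.harmonics, config.period, times)

    # patch labels from the (static) cap planes
    x0 = frames[0]
    labels = np.full(len(faces), WALL, dtype=object)
    # caps are planar to within the softened-junction deviation (~1e-4 cm)
    cap_tol = max(1e-8, 2e-2 * config.blend) if config.blend > 0 else 1e-8
    for spec in specs_body:
        on_plane = np.abs(x0 @ spec.d - spec.length) < cap_tol
        cap = np.all(on_plane[faces], axis=1)
        labels[cap] = spec.name
    if config.laa is not None:
        sd = (x0 - ostium_point) @ ostium_normal
        straddle = np.any(sd[faces] > 0, axis=1) & np.any(sd[faces] < 0, axis=1)
        labels[straddle] = LAA_OSTIUM_RING

    mesh = LASurfaceMesh(coeffs=coeffs, faces=faces, patch_labels=np.asarray(labels),
                         period=config.period, veins=tuple(config.veins), mv=config.mv,
                         laa=config.laa, ostium_point=ostium_point,
                         ostium_normal=ostium_normal, fit_residual=residual)
    mesh.check_closed()

    # verify the Fourier-projected mesh still hits the volume markers
    sac = (lambda t: laa_volume(mesh, t)) if config.laa is not None else (lambda t: 0.0)
    for key, target in (("t_min", config.v_min), ("t_max", config.v_max), ("t_pre_a", config.v_pre_a)):
        tk = la_wf.markers[key]
        got = enclosed_volume(mesh, tk) - sac(tk)
        if abs(got - target) > 0.02 * target:
            raise RuntimeError(f"volume marker {key} missed: requested {target:.3g}, got {got:.3g}; "
                               "increase harmonics or n_time")
    return mesh, la_wf, lv_wf, laa_wf


def _volume_beyond_plane(x: np.ndarray, faces: np.ndarray, p0: np.ndarray,
                         n: np.ndarray) -> float:
    """Volume enclosed between the surface and the half-space (x-p0).n > 0.

    Divergence theorem on the surface clipped to the half-space; fluxes are
    taken of the field (x - p0)/dim so the closing disc on the plane
    contributes nothing.
    """
    dim = x.shape[1]
    sd = (x - p0) @ n
    s_f = sd[faces]
    full = np.all(s_f >= 0, axis=1)
    straddle = np.any(s_f > 0, axis=1) & np.any(s_f < 0, axis=1)
    q = x - p0
    vol = 0.0
    if np.any(full):
        f = faces[full]
        if dim == 2:
            vol += 0.5 * float(np.sum(_cross2(q[f[:, 0]], q[f[:, 1]])))
        else:
            vol += float(np.sum(np.einsum("ij,ij->i", q[f[:, 0]],
                                          np.cross(q[f[:, 1]], q[f[:, 2]])))) / 6.0
    for face in faces[straddle]:
        s = sd[face]
        poly = []
        m = len(face)
        for i in range(m):
            a, b = face[i], face[(i + 1) % m]
            sa, sb = sd[a], sd[b]
            if sa >= 0:
                poly.append(q[a])
            if (sa > 0) != (sb > 0):
                lam = sa / (sa - sb)
                poly.append(q[a] + lam * (q[b] - q[a]))
        if dim == 2:
            if len(poly) >= 2:
                vol += 0.5 * float(_cross2(poly[0], poly[1]))
        else:
            for i in range(1, len(poly) - 1):
                vol += float(np.dot(poly[0], np.cross(poly[i], poly[i + 1]))) / 6.0
    return abs(vol)


def laa_volume(mesh: LASurfaceMesh, t: float) -> float:
    """Appendage volume (the part of the chamber beyond the ostium plane)."""
    if mesh.ostium_point is None:
        return 0.0
    return _volume_beyond_plane(mesh.positions(t), mesh.faces,
                                mesh.ostium_point, mesh.ostium_normal)
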