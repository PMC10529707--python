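"""Incompressible Navier-Stokes on a fixed Cartesian grid with immersed
moving walls.

Fractional-step (projection) solver on a uniform staggered MAC grid:

* three-stage low-storage Runge-Kutta in time with explicit advection and
  semi-implicit (Crank-Nicolson) viscosity, using the classical coefficient
  set gamma = (8/15, 5/12, 3/4), zeta = (0, -17/60, -5/12);
* second-order centered finite differences in space;
* a cosine-transform Poisson solve consistent with the free-slip box
  boundaries, giving exact discrete divergence removal;
* direct-forcing immersed-boundary treatment of the moving chamber wall with
  a three-point regularized delta kernel; the mitral orifice is capped by an
  impermeable immersed surface while the valve is shut and left open (a hole
  into the exterior of the box, which acts as the reservoir/sink) while it is
  open;
* pulmonary-vein inflow imposed in buffer regions upstream of each inlet cap,
  where the velocity is driven to the per-vein target Q_i / A_i along the
  inward cap normal;
* the residence-time scalar co-advanced once per full step with the updated
  velocity (WENO3 + SSP-RK3, see :mod:`atriaflow.residence`).

Velocities in cm/s, pressure per unit density (cm^2/s^2), viscosity in
cm^2/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np
from scipy.fft import dctn, idctn
from scipy.linalg import solve_banded

from .grid import CartesianGrid
from .inflow import InflowSchedule
from .residence import advance_tr

__all__ = ["SolverConfig", "FlowState", "IBMSolver", "CFLError", "RunResult", "run_case"]

RK_GAMMA = (8.0 / 15.0, 5.0 / 12.0, 3.0 / 4.0)
RK_ZETA = (0.0, -17.0 / 60.0, -5.0 / 12.0)


class CFLError(RuntimeError):
    pass


@dataclass
class SolverConfig:
    """Numerical parameters of the flow solver."""

    nu: float = 0.04            # kinematic viscosity, cm^2/s
    rho: float = 1.0            # g/cm^3 (pressure is stored as p/rho)
    dt: float = 1e-3            # s, constant within a run
    cfl_limit: float = 0.3      # hard stability/accuracy bound, checked each step
    ibm_iterations: int = 2     # direct-forcing sweeps per forcing pass
    ibm_projection_pairs: int = 2  # (force, project) passes per substep
    buffer_cells: int = 3       # buffer depth upstream of each PV inlet plane
    point_spacing: float = 0.75  # Lagrangian marker spacing in units of h
    mv_ramp_fraction: float = 0.05  # smoothing of valve opening/closing
    weno_eps: float | None = None   # None: grid-scaled 10 h^2
    viscous_scheme: str = "auto"    # "cn" | "explicit" | "auto"

    def resolved_viscous_scheme(self, h: float) -> str:
        if self.viscous_scheme != "auto":
            return self.viscous_scheme
        # the Crank-Nicolson solves only pay off when the explicit diffusion
        # limit (nu dt / h^2 < 1/(2 dim)) is actually restrictive
        return "explicit" if self.nu * self.dt / h ** 2 < 0.05 else "cn"


@dataclass
class FlowState:
    """Velocity (face arrays), pressure and residence time at one instant."""

    u: list
    p: np.ndarray
    tr: np.ndarray
    t: float

    def copy(self) -> "FlowState":
        return FlowState([ud.copy() for ud in self.u], self.p.copy(),
                         self.tr.copy(), self.t)


# ---------------------------------------------------------------------------
# Spatial operators (free-slip box)
# ---------------------------------------------------------------------------

def _pad_edge(a, axis):
    return np.pad(a, [(1, 1) if e == axis else (0, 0) for e in range(a.ndim)], mode="edge")


def _centered_derivative(a, axis, h, mirror):
    """Centered first derivative; ``mirror`` pads with zero-gradient ghosts,
    otherwise end entries are left at zero (Dirichlet nodes are not updated)."""
    if mirror:
        p = _pad_edge(a, axis)
        sl_hi = [slice(None)] * a.ndim
        sl_lo = [slice(None)] * a.ndim
        sl_hi[axis] = slice(2, None)
        sl_lo[axis] = slice(0, -2)
        return (p[tuple(sl_hi)] - p[tuple(sl_lo)]) / (2.0 * h)
    out = np.zeros_like(a)
    core = [slice(None)] * a.ndim
    core[axis] = slice(1, -1)
    hi = [slice(None)] * a.ndim
    lo = [slice(None)] * a.ndim
    hi[axis] = slice(2, None)
    lo[axis] = slice(0, -2)
    out[tuple(core)] = (a[tuple(hi)] - a[tuple(lo)]) / (2.0 * h)
    return out


def _avg(a, axis):
    hi = [slice(None)] * a.ndim
    lo = [slice(None)] * a.ndim
    hi[axis] = slice(1, None)
    lo[axis] = slice(0, -1)
    return 0.5 * (a[tuple(hi)] + a[tuple(lo)])


def _advection(u: list, d: int, h: float) -> np.ndarray:
    """Convective term (u . grad) u_d at component-d faces."""
    a = u[d]
    dim = len(u)
    adv = a * _centered_derivative(a, d, h, mirror=False)
    for e in range(dim):
        if e == d:
            continue
        ue_cell = _avg(u[e], axis=e)                    # cell centers
        ue_face = _avg(_pad_edge(ue_cell, d), axis=d)   # component-d faces
        adv += ue_face * _centered_derivative(a, e, h, mirror=True)
    return adv


def _laplacian(a: np.ndarray, d: int, h: float) -> np.ndarray:
    """Laplacian of velocity component d with free-slip box closures."""
    out = np.zeros_like(a)
    for e in range(a.ndim):
        if e == d:
            core = [slice(None)] * a.ndim
            core[e] = slice(1, -1)
            hi = [slice(None)] * a.ndim
            lo = [slice(None)] * a.ndim
            hi[e] = slice(2, None)
            lo[e] = slice(0, -2)
            out[tuple(core)] += a[tuple(hi)] - 2.0 * a[tuple(core)] + a[tuple(lo)]
        else:
            p = _pad_edge(a, e)
            hi = [slice(None)] * a.ndim
            lo = [slice(None)] * a.ndim
            md = [slice(None)] * a.ndim
            hi[e] = slice(2, None)
            lo[e] = slice(0, -2)
            md[e] = slice(1, -1)
            out += p[tuple(hi)] - 2.0 * p[tuple(md)] + p[tuple(lo)]
    return out / h ** 2


def _cn_solve_axis(a: np.ndarray, axis: int, lam: float, dirichlet: bool) -> np.ndarray:
    """Solve (I - lam * D2) x = a along one axis (D2 in index units)."""
    m = a.shape[axis]
    x = np.moveaxis(a, axis, 0).reshape(m, -1).copy()
    if dirichlet:
        if m > 2:
            ab = np.zeros((3, m - 2))
            ab[0, 1:] = -lam
            ab[1, :] = 1.0 + 2.0 * lam
            ab[2, :-1] = -lam
            # boundary values (held fixed) enter the first/last interior rows
            rhs = x[1:-1].copy()
            rhs[0] += lam * x[0]
            rhs[-1] += lam * x[-1]
            x[1:-1] = solve_banded((1, 1), ab, rhs)
    else:
        ab = np.zeros((3, m))
        ab[0, 1:] = -lam
        ab[1, :] = 1.0 + 2.0 * lam
        ab[1, 0] = ab[1, -1] = 1.0 + lam   # zero-gradient ghost
        ab[2, :-1] = -lam
        x = solve_banded((1, 1), ab, x)
    out = np.moveaxis(x.reshape((m,) + a.shape[:axis] + a.shape[axis + 1:]), 0, axis)
    return np.ascontiguousarray(out)


class _PoissonDCT:
    """Neumann Poisson solver diagonalized by the type-II cosine transform."""

    def __init__(self, n, h):
        lam = np.zeros(n)
        for d, nd in enumerate(n):
            k = np.arange(nd)
            l1 = 2.0 * (np.cos(np.pi * k / nd) - 1.0) / h ** 2
            shape = [1] * len(n)
            shape[d] = nd
            lam = lam + l1.reshape(shape)
        lam.flat[0] = 1.0
        self._lam = lam

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        c = dctn(rhs, type=2, norm="ortho")
        c /= self._lam
        c.flat[0] = 0.0
        return idctn(c, type=2, norm="ortho")


# ---------------------------------------------------------------------------
# Regularized delta interpolation / spreading
# ---------------------------------------------------------------------------

def _roma_delta(r: np.ndarray) -> np.ndarray:
    """Three-point regularized delta kernel (partition of unity)."""
    ar = np.abs(r)
    w = np.zeros_like(r)
    near = ar <= 0.5
    mid = (ar > 0.5) & (ar <= 1.5)
    w[near] = (1.0 + np.sqrt(np.clip(1.0 - 3.0 * r[near] ** 2, 0.0, None))) / 3.0
    w[mid] = (5.0 - 3.0 * ar[mid]
              - np.sqrt(np.clip(1.0 - 3.0 * (1.0 - ar[mid]) ** 2, 0.0, None))) / 6.0
    return w


def _kernel_stencil(field_shape, g: np.ndarray):
    """Indices and weights of the 3^dim kernel stencil at fractional coords g."""
    dim = g.shape[1]
    base = np.rint(g).astype(int)
    if np.any(base < 1) or np.any(base > np.asarray(field_shape) - 2):
        raise ValueError("Lagrangian point outside the grid (or too close to the box)")
    idx, wts = [], []
    for off in product((-1, 0, 1), repeat=dim):
        node = base + np.asarray(off)
        w = np.ones(len(g))
        for e in range(dim):
            w *= _roma_delta(g[:, e] - node[:, e])
        idx.append(node)
        wts.append(w)
    return idx, wts


def interp_to_points(field: np.ndarray, g: np.ndarray) -> np.ndarray:
    idx, wts = _kernel_stencil(field.shape, g)
    out = np.zeros(len(g))
    for node, w in zip(idx, wts):
        out += w * field[tuple(node.T)]
    return out


def spread_from_points(field: np.ndarray, g: np.ndarray, values: np.ndarray):
    idx, wts = _kernel_stencil(field.shape, g)
    for node, w in zip(idx, wts):
        np.add.at(field, tuple(node.T), w * values)


# ---------------------------------------------------------------------------
# Solver
# ---------------------------------------------------------------------------

class IBMSolver:
    """Advance the chamber flow; optionally with no immersed body (box flow).

    Parameters
    ----------
    grid : CartesianGrid
    config : SolverConfig
    mesh : LASurfaceMesh or None — moving immersed boundary
    schedule : InflowSchedule or None — PV buffer forcing + valve state
    """

    def __init__(self, grid: CartesianGrid, config: SolverConfig,
                 mesh=None, schedule: InflowSchedule | None = None):
        self.grid = grid
        self.config = config
        self.mesh = mesh
        self.schedule = schedule
        self.poisson = _PoissonDCT(grid.n, grid.h)
        self._n_prev = None
        if mesh is not None:
            self._setup_lagrangian()
        self._sched_cache: dict = {}
        if schedule is not None:
            self._setup_buffers()
            r = [np.abs(schedule.mitral.lv.rate(t))
                 for t in np.linspace(0, schedule.period, 512, endpoint=False)]
            self._mv_rate_scale = max(1e-12, float(np.max(r)))

    # -- immersed boundary bookkeeping -----------------------------------

    def _duct_extensions(self):
        """Static markers continuing each PV tube wall through the buffer, so
        the forced inflow column is confined as it would be inside the vein."""
        mesh, h = self.mesh, self.grid.h
        target = self.config.point_spacing * h
        length = (self.config.buffer_cells + 4) * h
        pts = []
        for v in mesh.veins:
            d = v.d
            n_ax = max(2, int(np.ceil(length / target)))
            # start inside the tube so the extension overlaps the wall rim and
            # seals the corner at the inlet plane
            s = v.length - 2 * h + np.linspace(0.0, length, n_ax)
            # walls sit half a cell outside the forced column so the plug
            # does not collide with the no-slip markers
            r_wall = v.radius + 0.5 * h
            if mesh.dim == 2:
                perp = np.array([-d[1], d[0]])
                for sign in (-1.0, 1.0):
                    pts.append(s[:, None] * d + sign * r_wall * perp)
            else:
                e1 = np.cross(d, [0.0, 0.0, 1.0])
                if np.linalg.norm(e1) < 1e-8:
                    e1 = np.cross(d, [0.0, 1.0, 0.0])
                e1 /= np.linalg.norm(e1)
                e2 = np.cross(d, e1)
                n_c = max(6, int(np.ceil(2 * np.pi * r_wall / target)))
                ang = np.linspace(0.0, 2.0 * np.pi, n_c, endpoint=False)
                ring = r_wall * (np.cos(ang)[:, None] * e1 + np.sin(ang)[:, None] * e2)
                for sk in s:
                    pts.append(sk * d + ring)
        if pts:
            all_pts = np.concatenate(pts)
            # keep markers where the delta kernel has full support in the box
            lo = np.asarray(self.grid.origin) + 1.5 * h
            hi = np.asarray(self.grid.origin) + np.asarray(self.grid.extent) - 1.5 * h
            keep = np.all((all_pts >= lo) & (all_pts <= hi), axis=1)
            self._duct_pts = all_pts[keep]
            self._duct_ds = np.full(len(self._duct_pts),
                                    target if mesh.dim == 2 else target ** 2 / h)
        else:
            self._duct_pts = np.zeros((0, mesh.dim))
            self._duct_ds = np.zeros(0)

    def _setup_lagrangian(self):
        mesh, h = self.mesh, self.grid.h
        target = self.config.point_spacing * h
        self._duct_extensions()
        if mesh.dim == 2:
            x0 = mesh.positions(0.0)
            seg = np.linalg.norm(np.diff(np.vstack([x0, x0[:1]]), axis=0), axis=1)
            # vertex i belongs to a patch if either adjacent boundary segment does
            lab = mesh.patch_labels
            prev = np.roll(lab, 1)
            open_vertex = np.zeros(mesh.n_vertices, dtype=bool)
            for v in mesh.veins:
                open_vertex |= (lab == v.name) & (prev == v.name)
            mv_vertex = (lab == "MV") | (prev == "MV")
            wall_idx, mv_idx, ds = [], [], []
            acc = target
            for i in range(mesh.n_vertices):
                acc += seg[i - 1] if i else 0.0
                if acc >= target:
                    if not open_vertex[i]:
                        (mv_idx if mv_vertex[i] else wall_idx).append(i)
                        ds.append(acc)
                    acc = 0.0
            spacing = float(np.median(ds)) if ds else target
            self._wall_idx = np.asarray(wall_idx, dtype=int)
            self._mv_idx = np.asarray(mv_idx, dtype=int)
            self._wall_ds = np.full(len(self._wall_idx), spacing)
            self._mv_ds = np.full(len(self._mv_idx), spacing)
            # markers in boundary order; only their Fourier rows are evaluated
            self._marker_idx = np.concatenate([self._wall_idx, self._mv_idx])
            order = np.argsort(self._marker_idx)
            self._marker_order = order
            self._marker_coeffs = mesh.coeffs[self._marker_idx]
            self._marker_is_mv = np.zeros(len(self._marker_idx), dtype=bool)
            self._marker_is_mv[len(self._wall_idx):] = True
        else:
            labels = self.mesh.patch_labels
            keep_wall = np.flatnonzero((labels == "wall") | (labels == "LAA_ostium_ring"))
            keep_mv = np.flatnonzero(labels == "MV")
            self._wall_faces = self.mesh.faces[keep_wall]
            self._mv_faces = self.mesh.faces[keep_mv]

    def _lagrangian(self, t: float):
        """Marker positions, velocities and quadrature weights (area/length).

        Marker velocities are projected onto the local surface normal: the
        synthetic anatomy prescribes the wall *shape* over time, and the
        tangential sliding of its parameterization is not material motion.
        """
        mesh = self.mesh
        if mesh.dim == 2:
            from .anatomy import fourier_eval_pair
            xs, vs = fourier_eval_pair(self._marker_coeffs, t, mesh.period)
            o = self._marker_order
            xo = xs[o]
            tang = np.roll(xo, -1, axis=0) - np.roll(xo, 1, axis=0)
            no = np.stack([tang[:, 1], -tang[:, 0]], axis=1)
            no /= np.maximum(np.linalg.norm(no, axis=1, keepdims=True), 1e-300)
            nrm = np.empty_like(no)
            nrm[o] = no
            vs = nrm * np.einsum("ij,ij->i", vs, nrm)[:, None]
            fac = np.where(self._marker_is_mv, self._mv_weight(t), 1.0)
            ds = np.concatenate([self._wall_ds, self._mv_ds])
            return self._with_ducts([xs], [vs], [ds], [fac])
        x = mesh.positions(t)
        v = mesh.velocities(t)
        # 3D: wall-face centroids weighted by face area
        def face_data(faces):
            p = x[faces].mean(axis=1)
            vv = v[faces].mean(axis=1)
            cr = np.cross(x[faces[:, 1]] - x[faces[:, 0]], x[faces[:, 2]] - x[faces[:, 0]])
            area = 0.5 * np.linalg.norm(cr, axis=1)
            nrm = cr / np.maximum(2.0 * area, 1e-300)[:, None]
            vv = nrm * np.einsum("ij,ij->i", vv, nrm)[:, None]
            return p, vv, area
        p, vv, area = face_data(self._wall_faces)
        pts, vel, ds, fac = [p], [vv], [area / self.grid.h], [np.ones(len(p))]
        w_mv = self._mv_weight(t)
        if w_mv > 0 and len(self._mv_faces):
            p, vv, area = face_data(self._mv_faces)
            pts.append(p)
            vel.append(vv)
            ds.append(area / self.grid.h)
            fac.append(np.full(len(p), w_mv))
        return self._with_ducts(pts, vel, ds, fac)

    def _with_ducts(self, pts, vel, ds, fac):
        if len(self._duct_pts):
            pts.append(self._duct_pts)
            vel.append(np.zeros_like(self._duct_pts))
            ds.append(self._duct_ds)
            fac.append(np.ones(len(self._duct_pts)))
        return (np.concatenate(pts), np.concatenate(vel),
                np.concatenate(ds), np.concatenate(fac))

    def _mv_weight(self, t: float) -> float:
        """1 while the valve is shut, 0 while open, with a smooth ramp around
        the transitions (the zeros of dV_LV/dt)."""
        if self.schedule is None:
            return 1.0
        rate = float(self.schedule.mitral.lv.rate(t))
        r0 = self.config.mv_ramp_fraction * self._mv_rate_scale
        return float(np.clip(-rate / r0, 0.0, 1.0))

    def _setup_buffers(self):
        grid, mesh = self.grid, self.mesh
        nb = self.config.buffer_cells
        self._buffers = []
        cells = grid.cell_centers()
        reset = np.zeros(int(np.prod(grid.n)), dtype=bool)
        lo = np.asarray(grid.origin) + grid.h
        hi = np.asarray(grid.origin) + np.asarray(grid.extent) - grid.h
        for v in mesh.veins:
            d = v.d
            per_component = []
            for comp in range(grid.dim):
                coords = _face_centers(grid, comp)
                ax = coords @ d
                perp = np.linalg.norm(coords - ax[:, None] * d, axis=1)
                m = (ax > v.length) & (ax <= v.length + nb * grid.h) & (perp <= v.radius)
                if np.any(m & (((coords < lo) | (coords > hi)).any(axis=1))):
                    raise ValueError(f"buffer of vein {v.name!r} touches the box boundary; "
                                     "enlarge the box")
                per_component.append(np.flatnonzero(m))
            ax = cells @ d
            perp = np.linalg.norm(cells - ax[:, None] * d, axis=1)
            reset |= (ax > v.length) & (ax <= v.length + (nb + 1) * grid.h) & (perp <= v.radius)
            self._buffers.append((v.name, d, per_component))
        self.tr_reset_mask = reset.reshape(grid.n)

    def _apply_buffers(self, u: list, t: float):
        # targets repeat every heartbeat; memoize on the cycle phase
        key = int(round((t % self.schedule.period) * 1e7))
        targets = self._sched_cache.get(key)
        if targets is None:
            targets = self.schedule.target_velocities(t)
            self._sched_cache[key] = targets
        for name, d, per_component in self._buffers:
            vt = targets[name]
            for comp in range(self.grid.dim):
                flat = u[comp].reshape(-1)
                flat[per_component[comp]] = vt[comp]

    # -- one time step ----------------------------------------------------

    def _project(self, u: list, adt: float):
        if self.grid.dim == 2:
            from ._kernels import divergence_2d, gradient_correct_2d
            psi = self.poisson.solve(divergence_2d(u[0], u[1], self.grid.h))
            gradient_correct_2d(u[0], u[1], psi, 1.0 / self.grid.h)
            return psi / adt
        div = self.grid.divergence(u)
        phi = self.poisson.solve(div / adt)
        h = self.grid.h
        for d in range(self.grid.dim):
            core = [slice(None)] * self.grid.dim
            core[d] = slice(1, -1)
            hi = [slice(None)] * self.grid.dim
            lo = [slice(None)] * self.grid.dim
            hi[d] = slice(1, None)
            lo[d] = slice(0, -1)
            u[d][tuple(core)] -= adt * (phi[tuple(hi)] - phi[tuple(lo)]) / h
        return phi

    def _zero_normal_boundaries(self, u: list):
        for d in range(self.grid.dim):
            first = [slice(None)] * self.grid.dim
            last = [slice(None)] * self.grid.dim
            first[d] = 0
            last[d] = -1
            u[d][tuple(first)] = 0.0
            u[d][tuple(last)] = 0.0

    def _terms(self, u: list):
        """Convective terms and Laplacians of every component."""
        h = self.grid.h
        if self.grid.dim == 2:
            from ._kernels import advection_laplacian_2d
            au, av, lu, lv = advection_laplacian_2d(u[0], u[1], h)
            return [au, av], [lu, lv]
        adv = [_advection(u, d, h) for d in range(self.grid.dim)]
        lap = [_laplacian(u[d], d, h) for d in range(self.grid.dim)]
        return adv, lap

    def _force_points(self, u: list, pts, vel, ds, fac):
        grid, cfg = self.grid, self.config
        h = grid.h
        fast = grid.dim == 2
        if fast:
            from ._kernels import interp_2d, spread_2d
        for d in range(grid.dim):
            g = grid.face_coord(d, pts)
            if fast:
                if np.any(np.rint(g) < 1) or np.any(np.rint(g) > np.asarray(u[d].shape) - 2):
                    raise ValueError("Lagrangian point outside the grid (or too close to the box)")
                gx = np.ascontiguousarray(g[:, 0])
                gy = np.ascontiguousarray(g[:, 1])
            for _ in range(cfg.ibm_iterations):
                cur = interp_2d(u[d], gx, gy) if fast else interp_to_points(u[d], g)
                force = (vel[:, d] - cur) * fac * (ds / h)
                if fast:
                    spread_2d(u[d], gx, gy, force)
                else:
                    spread_from_points(u[d], g, force)

    def step(self, state: FlowState) -> FlowState:
        cfg, grid = self.config, self.grid
        dt, h, nu = cfg.dt, grid.h, cfg.nu
        cfl = grid.max_cfl(state.u, dt)
        if cfl > cfg.cfl_limit:
            raise CFLError(f"CFL {cfl:.3f} exceeds the limit {cfg.cfl_limit} at t={state.t:.4f}")
        explicit_viscous = cfg.resolved_viscous_scheme(h) == "explicit"
        u = [ud.copy() for ud in state.u]
        t_sub = state.t
        phi = state.p
        for k in range(3):
            alpha = RK_GAMMA[k] + RK_ZETA[k]
            adt = alpha * dt
            t_next = t_sub + adt
            adv, lap = self._terms(u)
            n_cur = [-a for a in adv]
            visc_w = adt if explicit_viscous else 0.5 * adt
            for d in range(grid.dim):
                n_prev_d = n_cur[d] if self._n_prev is None else self._n_prev[d]
                if grid.dim == 2:
                    from ._kernels import fused_rhs_2d
                    rhs = fused_rhs_2d(u[d], dt * RK_GAMMA[k], n_cur[d],
                                       (0.0 if self._n_prev is None else dt * RK_ZETA[k]),
                                       n_prev_d, visc_w * nu, lap[d])
                else:
                    rhs = (u[d] + dt * RK_GAMMA[k] * n_cur[d]
                           + (0.0 if self._n_prev is None else dt * RK_ZETA[k]) * n_prev_d
                           + visc_w * nu * lap[d])
                if not explicit_viscous:
                    lam = 0.5 * adt * nu / h ** 2
                    for e in range(grid.dim):
                        rhs = _cn_solve_axis(rhs, e, lam, dirichlet=(e == d))
                u[d] = rhs
            self._n_prev = n_cur
            self._zero_normal_boundaries(u)
            # direct forcing interleaved with projection: re-forcing after the
            # pressure correction is what makes the immersed walls (nearly)
            # impermeable under the transvalvular pressure difference
            if self.mesh is not None or self.schedule is not None:
                pts = vel = ds = fac = None
                if self.mesh is not None:
                    pts, vel, ds, fac = self._lagrangian(t_next)
                for _ in range(self.config.ibm_projection_pairs):
                    if pts is not None:
                        self._force_points(u, pts, vel, ds, fac)
                    if self.schedule is not None:
                        self._apply_buffers(u, t_next)
                    self._zero_normal_boundaries(u)
                    phi = self._project(u, adt)
            else:
                self._zero_normal_boundaries(u)
                phi = self._project(u, adt)
            t_sub = t_next
        t_new = state.t + dt
        v_cell = grid.cell_velocity(u)
        reset = self.tr_reset_mask if self.schedule is not None else None
        tr = advance_tr(state.tr, v_cell, dt, h, reset_mask=reset, eps=cfg.weno_eps)
        return FlowState(u=u, p=phi, tr=tr, t=t_new)


def schedule_peak_velocity(mesh, lv_waveform, scenarios=("R60", "R55", "R50*", "eqV"),
                           n_time: int = 256) -> float:
    """Peak boundary-condition velocity over the cycle and the given scenarios
    (PV targets, mitral throughflow, wall-normal speed); used to pick dt."""
    from .anatomy import evaluate_mesh
    from .inflow import build_schedule
    a_mv = evaluate_mesh(mesh, 0.0).patch_area["MV"]
    tt = np.linspace(0.0, mesh.period, n_time, endpoint=False)
    vmax = _max_normal_wall_speed(mesh)
    for sc in scenarios:
        schedule = build_schedule(mesh, lv_waveform, sc)
        areas = schedule.areas(0.0)
        for t in tt:
            q = schedule.q_veins(t)
            vmax = max(vmax, max(abs(q[k]) / areas[k] for k in q))
            vmax = max(vmax, float(schedule.mitral.q_mv(t)) / a_mv)
    return vmax


def _max_normal_wall_speed(mesh, n_time: int = 64) -> float:
    """Peak wall-normal surface speed over the cycle."""
    out = 0.0
    for t in np.linspace(0.0, mesh.period, n_time, endpoint=False):
        x = mesh.positions(t)
        v = mesh.velocities(t)
        if mesh.dim == 2:
            tang = np.roll(x, -1, axis=0) - np.roll(x, 1, axis=0)
            nrm = np.stack([tang[:, 1], -tang[:, 0]], axis=1)
        else:
            f = mesh.faces
            nrm_f = np.cross(x[f[:, 1]] - x[f[:, 0]], x[f[:, 2]] - x[f[:, 0]])
            v = (v[f[:, 0]] + v[f[:, 1]] + v[f[:, 2]]) / 3.0
            nrm = nrm_f
        nrm = nrm / np.maximum(np.linalg.norm(nrm, axis=1, keepdims=True), 1e-300)
        out = max(out, float(np.max(np.abs(np.einsum("ij,ij->i", v, nrm)))))
    return out


def _face_centers(grid: CartesianGrid, d: int) -> np.ndarray:
    axes = []
    for e in range(grid.dim):
        if e == d:
            axes.append(grid.origin[e] + np.arange(grid.n[e] + 1) * grid.h)
        else:
            axes.append(grid.origin[e] + (np.arange(grid.n[e]) + 0.5) * grid.h)
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.stack([m.ravel() for m in mesh], axis=1)


# ---------------------------------------------------------------------------
# Case runner
# ---------------------------------------------------------------------------

@dataclass
class RunResult:
    """Snapshots over the averaging window plus run metadata."""

    grid: CartesianGrid
    times: np.ndarray            # snapshot times, s
    u_cell: np.ndarray           # (n_t, *n, dim) cell-centered velocity
    tr: np.ndarray               # (n_t, *n) residence time
    schedule: InflowSchedule
    manifest: dict


def _interp_field(src: CartesianGrid, dst: CartesianGrid, arr: np.ndarray, comp: int | None):
    from scipy.interpolate import RegularGridInterpolator
    def axes(grid, shape):
        out = []
        for e, m in enumerate(shape):
            if comp is not None and e == comp:
                out.append(grid.origin[e] + np.arange(m) * grid.h)
            else:
                out.append(grid.origin[e] + (np.arange(m) + 0.5) * grid.h)
        return out
    rgi = RegularGridInterpolator(axes(src, arr.shape), arr, bounds_error=False, fill_value=None)
    shape = dst.face_shape(comp) if comp is not None else dst.n
    mesh = np.meshgrid(*axes(dst, shape), indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=1)
    return rgi(pts).reshape(shape)


def run_case(mesh, lv_waveform, scenario, grid: CartesianGrid,
             config: SolverConfig | None = None, warmup_cycles: int = 2,
             cycles: int = 3, coarsen: int = 2, snapshots_per_cycle: int = 32,
             cfl_target: float = 0.24, velocity_safety: float = 1.8,
             vmax: float | None = None, progress: bool = False) -> RunResult:
    """Simulate one anatomy under one flow-split scenario.

    Runs ``warmup_cycles`` heartbeats on a ``coarsen``-times coarser grid to
    approach the periodic regime cheaply, interpolates to the nominal grid and
    runs ``cycles`` more heartbeats, which form the averaging window returned
    as snapshots.  The constant time step is set from ``cfl_target`` against
    the peak schedule velocity times ``velocity_safety``.
    """
    from .inflow import build_schedule
    schedule = build_schedule(mesh, lv_waveform, scenario)
    period = mesh.period

    if vmax is None:
        vmax = schedule_peak_velocity(mesh, lv_waveform)
    vmax = max(vmax, 1.0) * velocity_safety

    base = config or SolverConfig()
    results_manifest = {"scenario": getattr(scenario, "name", str(scenario)),
                        "vmax_design": vmax, "cycles": []}

    def make_level(factor):
        n = tuple(nd // factor for nd in grid.n)
        g = CartesianGrid(n=n, h=grid.h * factor, origin=grid.origin)
        n_steps = int(np.ceil(period * vmax / (cfl_target * g.h)))
        # the coarse warm-up only has to spin the flow up; its under-resolved
        # immersed boundary spikes harder, so it gets a looser (still stable)
        # advective guard while the nominal level keeps the strict limit
        limit = base.cfl_limit if factor == 1 else max(base.cfl_limit, 0.6)
        cfg = replace(base, dt=period / n_steps, cfl_limit=limit)
        return g, cfg, n_steps

    state = None
    if warmup_cycles > 0 and coarsen > 1:
        g_c, cfg_c, n_steps_c = make_level(coarsen)
        solver = IBMSolver(g_c, cfg_c, mesh=mesh, schedule=schedule)
        state = FlowState(g_c.zero_velocity(), g_c.zero_cells(), g_c.zero_cells(), 0.0)
        for c in range(warmup_cycles):
            for _ in range(n_steps_c):
                state = solver.step(state)
            results_manifest["cycles"].append(
                {"level": "coarse", "t": state.t,
                 "max_div": float(np.max(np.abs(g_c.divergence(state.u))))})

    g_f, cfg_f, n_steps_f = make_level(1)
    solver = IBMSolver(g_f, cfg_f, mesh=mesh, schedule=schedule)
    if state is None:
        state = FlowState(g_f.zero_velocity(), g_f.zero_cells(), g_f.zero_cells(), 0.0)
    else:
        u_f = [_interp_field(g_c, g_f, state.u[d], d) for d in range(g_f.dim)]
        tr_f = _interp_field(g_c, g_f, state.tr, None)
        state = FlowState(u_f, g_f.zero_cells(), np.clip(tr_f, 0.0, None), state.t)
        solver._zero_normal_boundaries(state.u)
        solver._project(state.u, 1.0)

    snap_every = max(1, n_steps_f // snapshots_per_cycle)
    times, us, trs = [], [], []
    for c in range(cycles):
        for i in range(n_steps_f):
            state = solver.step(state)
            if (i + 1) % snap_every == 0:
                times.append(state.t)
                us.append(g_f.cell_velocity(state.u))
                trs.append(state.tr.copy())
        results_manifest["cycles"].append(
            {"level": "fine", "t": state.t,
             "max_cfl": g_f.max_cfl(state.u, cfg_f.dt),
             "max_div": float(np.max(np.abs(g_f.divergence(state.u))))})
        if progress:
            print(f"  cycle {c + 1}/{cycles} done, t={state.t:.2f}s")
    results_manifest["dt"] = cfg_f.dt
    results_manifest["n_steps_per_cycle"] = n_steps_f
    return RunResult(grid=g_f, times=np.asarray(times), u_cell=np.stack(us),
                     tr=np.stack(trs), schedule=schedule, manifest=results_manifest)
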