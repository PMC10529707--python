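"""Compiled inner loops for the planar (2D) solver hot path.

These numba kernels mirror the vectorized numpy reference implementations in
:mod:`atriaflow.solver` and :mod:`atriaflow.residence` (which remain the
documentation of record and serve the 3D path); unit tests assert agreement
between the two routes.  No fastmath: results are bit-stable across runs.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["weno3_rhs_2d", "advection_laplacian_2d", "interp_2d", "spread_2d",
           "fused_rhs_2d", "divergence_2d", "gradient_correct_2d"]


@njit(cache=True)
def fused_rhs_2d(u, a, n_cur, b, n_prev, c, lap):
    """u + a*n_cur + b*n_prev + c*lap in one pass."""
    out = np.empty_like(u)
    for i in range(u.shape[0]):
        for j in range(u.shape[1]):
            out[i, j] = u[i, j] + a * n_cur[i, j] + b * n_prev[i, j] + c * lap[i, j]
    return out


@njit(cache=True)
def divergence_2d(u, v, h):
    nx, ny = v.shape[0], u.shape[1]
    out = np.empty((nx, ny))
    inv_h = 1.0 / h
    for i in range(nx):
        for j in range(ny):
            out[i, j] = (u[i + 1, j] - u[i, j] + v[i, j + 1] - v[i, j]) * inv_h
    return out


@njit(cache=True)
def gradient_correct_2d(u, v, phi, adt_over_h):
    nx, ny = phi.shape
    for i in range(1, nx):
        for j in range(ny):
            u[i, j] -= adt_over_h * (phi[i, j] - phi[i - 1, j])
    for i in range(nx):
        for j in range(1, ny):
            v[i, j] -= adt_over_h * (phi[i, j] - phi[i, j - 1])


@njit(cache=True)
def _weno_pair(a, b, c, eps):
    # biased derivative: (b + c)/2 - w (c - 2b + a)/2 with smoothness ratio r
    r = (eps + (b - a) ** 2) / (eps + (c - b) ** 2)
    w = 1.0 / (1.0 + 2.0 * r * r)
    return 0.5 * (b + c) - 0.5 * w * (c - 2.0 * b + a)


@njit(cache=True)
def weno3_rhs_2d(tr, vx, vy, h, eps, source, periodic=False):
    """RHS of dTR/dt = source - v.grad(TR) with WENO3 upwinding; ghosts are
    zero-gradient or periodic."""
    nx, ny = tr.shape
    out = np.empty_like(tr)
    inv_h = 1.0 / h
    for i in range(nx):
        if periodic:
            im2 = (i - 2) % nx; im1 = (i - 1) % nx
            ip1 = (i + 1) % nx; ip2 = (i + 2) % nx
        else:
            im2 = max(i - 2, 0); im1 = max(i - 1, 0)
            ip1 = min(i + 1, nx - 1); ip2 = min(i + 2, nx - 1)
        for j in range(ny):
            if periodic:
                jm2 = (j - 2) % ny; jm1 = (j - 1) % ny
                jp1 = (j + 1) % ny; jp2 = (j + 2) % ny
            else:
                jm2 = max(j - 2, 0); jm1 = max(j - 1, 0)
                jp1 = min(j + 1, ny - 1); jp2 = min(j + 2, ny - 1)
            acc = source
            # x-direction differences D^- at i-1, i, i+1, i+2
            v1 = (tr[im1, j] - tr[im2, j]) * inv_h
            v2 = (tr[i, j] - tr[im1, j]) * inv_h
            v3 = (tr[ip1, j] - tr[i, j]) * inv_h
            u1 = (tr[ip2, j] - tr[ip1, j]) * inv_h
            vel = vx[i, j]
            if vel > 0.0:
                acc -= vel * _weno_pair(v1, v2, v3, eps)
            elif vel < 0.0:
                acc -= vel * _weno_pair(u1, v3, v2, eps)
            v1 = (tr[i, jm1] - tr[i, jm2]) * inv_h
            v2 = (tr[i, j] - tr[i, jm1]) * inv_h
            v3 = (tr[i, jp1] - tr[i, j]) * inv_h
            u1 = (tr[i, jp2] - tr[i, jp1]) * inv_h
            vel = vy[i, j]
            if vel > 0.0:
                acc -= vel * _weno_pair(v1, v2, v3, eps)
            elif vel < 0.0:
                acc -= vel * _weno_pair(u1, v3, v2, eps)
            out[i, j] = acc
    return out


@njit(cache=True)
def advection_laplacian_2d(u, v, h):
    """Convective terms and Laplacians of both MAC components.

    Returns (adv_u, adv_v, lap_u, lap_v) with free-slip closures: mirrored
    tangential ghosts, Dirichlet ends untouched (left zero).
    """
    nxu, nyu = u.shape   # (nx+1, ny)
    nxv, nyv = v.shape   # (nx, ny+1)
    adv_u = np.zeros_like(u)
    lap_u = np.zeros_like(u)
    adv_v = np.zeros_like(v)
    lap_v = np.zeros_like(v)
    inv2h = 0.5 / h
    inv_h2 = 1.0 / (h * h)
    for i in range(nxu):
        for j in range(nyu):
            jm = max(j - 1, 0)
            jp = min(j + 1, nyu - 1)
            lap = u[i, jp] - 2.0 * u[i, j] + u[i, jm]
            if 0 < i < nxu - 1:
                lap += u[i + 1, j] - 2.0 * u[i, j] + u[i - 1, j]
                dudx = (u[i + 1, j] - u[i - 1, j]) * inv2h
                # v averaged to the u point (cells i-1 and i share this face)
                vbar = 0.25 * (v[i - 1, j] + v[i - 1, j + 1] + v[i, j] + v[i, j + 1])
                dudy = (u[i, jp] - u[i, jm]) * inv2h  # mirrored ghosts at walls
                adv_u[i, j] = u[i, j] * dudx + vbar * dudy
            lap_u[i, j] = lap * inv_h2
    for i in range(nxv):
        for j in range(nyv):
            im = max(i - 1, 0)
            ip = min(i + 1, nxv - 1)
            lap = v[ip, j] - 2.0 * v[i, j] + v[im, j]
            if 0 < j < nyv - 1:
                lap += v[i, j + 1] - 2.0 * v[i, j] + v[i, j - 1]
                dvdy = (v[i, j + 1] - v[i, j - 1]) * inv2h
                ubar = 0.25 * (u[i, j - 1] + u[i + 1, j - 1] + u[i, j] + u[i + 1, j])
                dvdx = (v[ip, j] - v[im, j]) * inv2h
                adv_v[i, j] = ubar * dvdx + v[i, j] * dvdy
            lap_v[i, j] = lap * inv_h2
    return adv_u, adv_v, lap_u, lap_v


@njit(cache=True)
def _roma(r):
    ar = abs(r)
    if ar <= 0.5:
        t = 1.0 - 3.0 * r * r
        return (1.0 + np.sqrt(t if t > 0.0 else 0.0)) / 3.0
    if ar <= 1.5:
        t = 1.0 - 3.0 * (1.0 - ar) ** 2
        return (5.0 - 3.0 * ar - np.sqrt(t if t > 0.0 else 0.0)) / 6.0
    return 0.0


@njit(cache=True)
def interp_2d(field, gx, gy):
    npts = gx.shape[0]
    out = np.zeros(npts)
    for p in range(npts):
        bi = int(round(gx[p]))
        bj = int(round(gy[p]))
        acc = 0.0
        for oi in range(-1, 2):
            wi = _roma(gx[p] - (bi + oi))
            if wi == 0.0:
                continue
            for oj in range(-1, 2):
                wj = _roma(gy[p] - (bj + oj))
                if wj != 0.0:
                    acc += wi * wj * field[bi + oi, bj + oj]
        out[p] = acc
    return out


@njit(cache=True)
def spread_2d(field, gx, gy, values):
    npts = gx.shape[0]
    for p in range(npts):
        bi = int(round(gx[p]))
        bj = int(round(gy[p]))
        for oi in range(-1, 2):
            wi = _roma(gx[p] - (bi + oi))
            if wi == 0.0:
                continue
            for oj in range(-1, 2):
                wj = _roma(gy[p] - (bj + oj))
                if wj != 0.0:
                    field[bi + oi, bj + oj] += wi * wj * values[p]
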