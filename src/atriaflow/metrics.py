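"""Hemodynamic metrics: kinetic-energy decomposition, correlation factors
across flow-split scenarios, z-scores and the residence-time volume model.

The correlation factors are normalized inner products (cosine similarities,
no mean subtraction): for per-vein flow-rate waveforms

    rho_PV = (1/n) sum_k  <Q_k^i, Q_k^j> / (||Q_k^i|| ||Q_k^j||),

and for velocity fields a space-time inner product over a region mask,
optionally restricted to the components perpendicular or parallel to the
mitral-valve plane.  By Cauchy-Schwarz both lie in [-1, 1], equal 1 for
identical inputs and are invariant to positive rescaling.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

__all__ = ["ke_decompose", "correlation_pv", "correlation_la",
           "zscore_across_splits", "tr_body_model", "box_percentiles"]

PERCENTILES = (9, 25, 50, 75, 91)  # box-and-whisker convention


def ke_decompose(v: np.ndarray, mask: np.ndarray, normal: np.ndarray):
    """Mean kinetic energy per unit mass, split along the MV-plane normal.

    ``v`` has shape (..., dim) over grid cells, ``mask`` selects the region.
    Returns ``(ke_perp, ke_par)`` with ke_perp = <(v.n)^2>/2 and
    ke_par = <|v - (v.n)n|^2>/2; their sum is the total mean KE.
    """
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    if not np.any(mask):
        raise ValueError("empty region mask")
    vm = v[mask]
    vn = vm @ n
    ke_perp = 0.5 * float(np.mean(vn ** 2))
    ke_par = 0.5 * float(np.mean(np.sum((vm - vn[:, None] * n) ** 2, axis=1)))
    return ke_perp, ke_par


def _time_weights(t: np.ndarray) -> np.ndarray:
    """Trapezoidal quadrature weights for possibly irregular samples."""
    t = np.asarray(t, dtype=float)
    if len(t) == 1:
        return np.ones(1)
    w = np.empty_like(t)
    w[0] = 0.5 * (t[1] - t[0])
    w[-1] = 0.5 * (t[-1] - t[-2])
    w[1:-1] = 0.5 * (t[2:] - t[:-2])
    return w


def correlation_pv(q_i: dict, q_j: dict, t: np.ndarray) -> float:
    """Correlation factor of per-vein flow-rate waveforms between two splits.

    ``q_i`` and ``q_j`` map vein names to sampled waveforms on the common
    times ``t``.  Average of per-vein normalized inner products.
    """
    if set(q_i) != set(q_j):
        raise ValueError("the two splits carry different vein sets")
    w = _time_weights(t)
    vals = []
    for k in q_i:
        a = np.asarray(q_i[k], dtype=float)
        b = np.asarray(q_j[k], dtype=float)
        na = np.sqrt(np.sum(w * a * a))
        nb = np.sqrt(np.sum(w * b * b))
        if na == 0.0 or nb == 0.0:
            raise ValueError(f"vein {k!r} has an identically zero waveform")
        vals.append(np.sum(w * a * b) / (na * nb))
    return float(np.mean(vals))


def correlation_la(u_i: np.ndarray, u_j: np.ndarray, mask: np.ndarray,
                   t: np.ndarray, normal: np.ndarray | None = None,
                   component: str = "full") -> float:
    """Correlation factor of two 4D velocity fields over a region.

    ``u_i``, ``u_j`` have shape (n_t, n_cells, dim) sampled on identical grid
    points and times; ``mask`` is (n_cells,) or (n_t, n_cells).  ``component``
    selects the full vector, the ``"perp"`` projection onto the MV normal, or
    the ``"par"`` complement.
    """
    u_i = np.asarray(u_i, dtype=float)
    u_j = np.asarray(u_j, dtype=float)
    if u_i.shape != u_j.shape:
        raise ValueError("velocity fields must share shape")
    if component != "full":
        n = np.asarray(normal, dtype=float)
        n = n / np.linalg.norm(n)
        pi = np.einsum("tcd,d->tc", u_i, n)
        pj = np.einsum("tcd,d->tc", u_j, n)
        if component == "perp":
            u_i = pi[..., None] * n
            u_j = pj[..., None] * n
        elif component == "par":
            u_i = u_i - pi[..., None] * n
            u_j = u_j - pj[..., None] * n
        else:
            raise ValueError("component must be 'full', 'perp' or 'par'")
    if mask.ndim == 1:
        mask = np.broadcast_to(mask, u_i.shape[:2])
    w = _time_weights(t)[:, None] * mask
    dot = np.sum(w * np.einsum("tcd,tcd->tc", u_i, u_j))
    ni = np.sum(w * np.einsum("tcd,tcd->tc", u_i, u_i))
    nj = np.sum(w * np.einsum("tcd,tcd->tc", u_j, u_j))
    if ni == 0.0 or nj == 0.0:
        raise ValueError("zero-norm velocity field over the region")
    return float(dot / np.sqrt(ni * nj))


def zscore_across_splits(stats) -> float:
    """Mean pairwise z-score of a quantity across flow splits.

    ``stats`` is a sequence of ``(mean, std)`` per split; returns
    mean over unordered pairs of |mu_j - mu_i| / sqrt(s_i^2 + s_j^2).
    """
    stats = [(float(m), float(s)) for m, s in stats]
    if len(stats) < 2:
        raise ValueError("need at least two splits")
    vals = []
    for (mi, si), (mj, sj) in combinations(stats, 2):
        denom = np.hypot(si, sj)
        if denom == 0.0:
            if mi == mj:
                vals.append(0.0)
                continue
            raise ValueError("zero variance with unequal means: z-score is infinite")
        vals.append(abs(mj - mi) / denom)
    return float(np.mean(vals))


def tr_body_model(lav: float, lvsv: float, alpha: float = 1.4) -> float:
    """Residence-time model for the atrial body, in cycles: TR = LAV/(alpha*LVSV).

    ``lav`` is the cycle-mean LA volume and ``lvsv`` the LV stroke volume;
    ``alpha > 1`` accounts for washout concentrated in early LV filling.
    """
    if lav <= 0 or lvsv <= 0 or alpha <= 0:
        raise ValueError("volumes and alpha must be positive")
    return lav / (alpha * lvsv)


def box_percentiles(values: np.ndarray, percentiles=PERCENTILES) -> dict:
    """The box-plot percentile set used for per-region summaries."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty sample")
    return {p: float(np.percentile(values, p)) for p in percentiles}
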