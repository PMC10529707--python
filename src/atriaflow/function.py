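"""Atrial functional parameters from volume waveforms and flow schedules.

These are the standard volumetric and Doppler-style indices of left-atrial
function:

* global EF            (V_LA,max - V_LA,min) / V_LA,max
* LAA EF               (V_LAA,max - V_LAA,min) / V_LAA,max
* LV EF                (V_LV,max - V_LV,min) / V_LV,max
* expansion index      (V_LA,max - V_LA,min) / V_LA,min
* passive EF           (V_LA,max - V_LA,preA) / V_LA,max
* booster EF           (V_LA,preA - V_LA,min) / V_LA,preA
* conduit fraction     1 - (V_LA,max - V_LA,min) / LVSV
* PVs / PVd / PVa      PV volumes entering during LV systole / diastole, and
                       the reverse (atrial-kick) volume, with phase durations
* E/A ratio            ratio of peak early to peak late transmitral velocity
* Re_MV                mitral Reynolds number u_E * D_MV / nu with
                       D_MV = sqrt(4 A_MV / pi)

A small bundled cohort table of published per-subject functional parameters
(five subjects in sinus rhythm with normal atrial function, three with
persistent AF and LAA thrombus or prior TIAs) serves as reference input for
the index formulas and the group statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .inflow import MitralSchedule
from .waveforms import VolumeWaveform

__all__ = [
    "FunctionRecord", "volume_indices", "ejection_fractions",
    "pv_phase_volumes", "mitral_wave_metrics", "group_stats", "pearson",
    "load_reference_cohort", "recompute_cohort_indices", "ostium_metrics",
]

KINEMATIC_VISCOSITY = 0.04  # cm^2/s, blood


@dataclass
class FunctionRecord:
    """Computed functional parameters; volume-derived fields in ml, durations
    in cycles, EFs dimensionless."""

    v_la_min: float | None = None
    v_la_max: float | None = None
    v_la_pre_a: float | None = None
    v_laa_min: float | None = None
    v_laa_max: float | None = None
    lvsv: float | None = None
    global_ef: float | None = None
    laa_ef: float | None = None
    lv_ef: float | None = None
    passive_ef: float | None = None
    booster_ef: float | None = None
    expansion_index: float | None = None
    conduit_fraction: float | None = None
    pvs: float | None = None
    pvd: float | None = None
    pvs_pvd_ratio: float | None = None
    pva: float | None = None
    pva_duration: float | None = None
    a_wave_duration: float | None = None
    e_a_ratio: float | None = None
    re_mv: float | None = None
    flags: dict = field(default_factory=dict)

    def rounded(self, decimals: int = 2) -> dict:
        """Non-null fields rounded for table comparison."""
        out = {}
        for k, v in self.__dict__.items():
            if isinstance(v, float):
                out[k] = round(v, decimals)
        return out


def volume_indices(v_la_min: float, v_la_max: float, v_la_pre_a: float,
                   lvsv: float, v_laa_min: float | None = None,
                   v_laa_max: float | None = None, v_lv_min: float | None = None,
                   v_lv_max: float | None = None) -> FunctionRecord:
    """All volume-derived indices, applied verbatim from chamber volumes."""
    if not (v_la_min <= v_la_pre_a <= v_la_max):
        raise ValueError("markers out of order: need V_min <= V_preA <= V_max")
    rec = FunctionRecord(v_la_min=v_la_min, v_la_max=v_la_max,
                         v_la_pre_a=v_la_pre_a, lvsv=lvsv,
                         v_laa_min=v_laa_min, v_laa_max=v_laa_max)
    rec.global_ef = (v_la_max - v_la_min) / v_la_max
    rec.expansion_index = (v_la_max - v_la_min) / v_la_min if v_la_min > 0 else 0.0
    rec.passive_ef = (v_la_max - v_la_pre_a) / v_la_max
    rec.booster_ef = (v_la_pre_a - v_la_min) / v_la_pre_a
    rec.conduit_fraction = 1.0 - (v_la_max - v_la_min) / lvsv
    if v_laa_min is not None and v_laa_max is not None:
        rec.laa_ef = (v_laa_max - v_laa_min) / v_laa_max
    if v_lv_min is not None and v_lv_max is not None:
        rec.lv_ef = (v_lv_max - v_lv_min) / v_lv_max
    return rec


def ejection_fractions(la: VolumeWaveform, laa: VolumeWaveform | None = None,
                       lv: VolumeWaveform | None = None) -> FunctionRecord:
    """Volume-derived indices from waveform markers."""
    m = la.markers
    for key in ("t_min", "t_max", "t_pre_a"):
        if key not in m:
            raise ValueError(f"LA waveform lacks marker {key!r}")
    kwargs = {}
    if laa is not None:
        kwargs["v_laa_min"] = float(laa.volume(laa.markers["t_min"]))
        kwargs["v_laa_max"] = float(laa.volume(laa.markers["t_max"]))
    lvsv = None
    if lv is not None:
        v_lv_max = float(lv.volume(lv.markers["t_max"]))
        v_lv_min = float(lv.volume(lv.markers["t_min"]))
        lvsv = v_lv_max - v_lv_min
        kwargs.update(v_lv_min=v_lv_min, v_lv_max=v_lv_max)
    if lvsv is None:
        raise ValueError("an LV waveform is required to define LVSV")
    return volume_indices(float(la.volume(m["t_min"])), float(la.volume(m["t_max"])),
                          float(la.volume(m["t_pre_a"])), lvsv, **kwargs)


def _diastole_window(mitral: MitralSchedule, t: np.ndarray):
    """Contiguous diastolic span [first valve opening, last closure)."""
    open_ = mitral.mv_open(t)
    if not open_.any():
        raise ValueError("the mitral valve never opens: no diastole")
    idx = np.flatnonzero(open_)
    return t[idx[0]], t[idx[-1]]


def _a_wave_onset(mitral: MitralSchedule, t: np.ndarray, t_open: float, t_close: float):
    """Onset of the late-diastolic (atrial-kick) transmitral wave: the last
    local minimum of Q_MV strictly inside diastole before valve closure.
    Returns None for monophasic (AF-like) filling."""
    sel = (t > t_open) & (t < t_close)
    ts, qs = t[sel], mitral.q_mv(t[sel])
    if len(ts) < 5:
        return None
    interior = (qs[1:-1] <= qs[:-2]) & (qs[1:-1] <= qs[2:]) & (qs[1:-1] < 0.5 * qs.max())
    mins = np.flatnonzero(interior) + 1
    # require a rise after the minimum (a genuine second wave)
    for i in reversed(mins):
        if qs[i:].max() > qs[i] + 1e-9 * max(1.0, qs.max()):
            return float(ts[i])
    return None


def pv_phase_volumes(q_pv, mitral: MitralSchedule, period: float,
                     n: int = 8192) -> FunctionRecord:
    """PVs, PVd, PVa volumes and phase durations by numerical quadrature.

    ``q_pv`` is a callable of time (ml/s).  PVs integrates forward PV inflow
    while the mitral valve is shut (LV systole), PVd while it is open, and
    PVa the reverse flow during the atrial contraction window.
    """
    t = np.linspace(0.0, period, n, endpoint=False)
    dt = period / n
    q = np.asarray(q_pv(t), dtype=float)
    open_ = mitral.mv_open(t)
    t_open, t_close = _diastole_window(mitral, t)
    diast = (t >= t_open) & (t <= t_close)
    rec = FunctionRecord()
    rec.pvs = float(np.sum(np.maximum(q[~diast], 0.0)) * dt)
    rec.pvd = float(np.sum(np.maximum(q[diast], 0.0)) * dt)
    rec.pvs_pvd_ratio = rec.pvs / rec.pvd if rec.pvd > 0 else np.nan
    t_a = _a_wave_onset(mitral, t, t_open, t_close)
    if t_a is None:
        rec.flags["monophasic"] = True
        a_win = diast  # fall back: any reversal during diastole
        rec.a_wave_duration = None
    else:
        a_win = (t >= t_a) & (t <= t_close)
        rec.a_wave_duration = (t_close - t_a) / period
    rec.pva = float(np.sum(np.maximum(-q[a_win], 0.0)) * dt)
    rec.pva_duration = float(np.sum((q < 0) & a_win) * dt / period)
    return rec


def mitral_wave_metrics(mitral: MitralSchedule, a_mv: float,
                        nu: float = KINEMATIC_VISCOSITY, n: int = 8192) -> FunctionRecord:
    """E/A velocity ratio and the mitral Reynolds number.

    Peak velocities are u = Q_MV / A_MV in the early (E) and late (A)
    diastolic windows; Re_MV = u_E D_MV / nu with D_MV = sqrt(4 A_MV / pi).
    Monophasic filling (no A wave) leaves E/A undefined and flagged.
    """
    if a_mv <= 0:
        raise ValueError("mitral area must be positive")
    period = mitral.period
    t = np.linspace(0.0, period, n, endpoint=False)
    t_open, t_close = _diastole_window(mitral, t)
    t_a = _a_wave_onset(mitral, t, t_open, t_close)
    rec = FunctionRecord()
    q = mitral.q_mv(t)
    if t_a is None:
        rec.flags["monophasic"] = True
        u_e = float(q.max()) / a_mv
        rec.e_a_ratio = None
    else:
        e_win = (t >= t_open) & (t < t_a)
        a_win = (t >= t_a) & (t <= t_close)
        u_e = float(q[e_win].max()) / a_mv
        u_a = float(q[a_win].max()) / a_mv
        if u_a <= 0:
            rec.flags["monophasic"] = True
            rec.e_a_ratio = None
        else:
            rec.e_a_ratio = u_e / u_a
    d_mv = np.sqrt(4.0 * a_mv / np.pi)
    rec.re_mv = u_e * d_mv / nu
    return rec


# ---------------------------------------------------------------------------
# Cohort statistics
# ---------------------------------------------------------------------------

def load_reference_cohort() -> pd.DataFrame:
    """Published per-subject functional parameters of an eight-subject cohort
    (subjects 1-5 normal, 6-8 impaired/pro-thrombotic)."""
    with resources.files("atriaflow.data").joinpath("cohort_function.csv").open() as f:
        return pd.read_csv(f)


def recompute_cohort_indices(cohort: pd.DataFrame | None = None) -> pd.DataFrame:
    """Re-derive every volume-derived index from the cohort's printed volumes.

    Returns a frame with recomputed values rounded to the table's 2-decimal
    precision alongside the published ones.
    """
    df = load_reference_cohort() if cohort is None else cohort
    rows = []
    for _, r in df.iterrows():
        rec = volume_indices(r.v_la_min_ml, r.v_la_max_ml, r.v_la_pre_a_ml,
                             r.lvsv_ml, r.v_laa_min_ml, r.v_laa_max_ml)
        rows.append({
            "subject": int(r.subject),
            "global_ef": round(rec.global_ef, 2),
            "laa_ef": round(rec.laa_ef, 2),
            "expansion_index": round(rec.expansion_index, 2),
            "passive_ef": round(rec.passive_ef, 2),
            "booster_ef": round(rec.booster_ef, 2),
            "conduit_fraction": round(rec.conduit_fraction, 2),
            "pvs_pvd_ratio": round(r.pvs_ml / r.pvd_ml, 2),
        })
    return pd.DataFrame(rows).set_index("subject")


def group_stats(df: pd.DataFrame, column: str, group: str = "group") -> pd.DataFrame:
    """Per-group mean and sample (n-1) standard deviation of a column."""
    g = df.groupby(group)[column]
    out = g.agg(["mean", "std", "count"])
    if (out["count"] < 2).any():
        raise ValueError("need at least two subjects per group for a std")
    return out


def pearson(df: pd.DataFrame, x: str, y: str):
    """Pearson correlation with two-sided t-test p-value."""
    if len(df) < 3:
        raise ValueError("need at least three subjects for a correlation")
    if df[x].std() == 0 or df[y].std() == 0:
        raise ValueError("degenerate (constant) column in correlation")
    r = sstats.pearsonr(df[x], df[y])
    return float(r.statistic), float(r.pvalue)


def ostium_metrics(mesh, n_time: int = 16):
    """Time-averaged appendage-ostium area (cm^2) and aspect ratio.

    The aspect ratio is the major/minor axis ratio of the ostium ring's
    second-moment ellipse.
    """
    from .anatomy import ostium_ring
    areas, ars = [], []
    for tk in np.linspace(0.0, mesh.period, n_time, endpoint=False):
        pts = ostium_ring(mesh, tk)
        c = pts.mean(axis=0)
        q = pts - c
        if mesh.dim == 2:
            areas.append(float(np.linalg.norm(q[0] - q[-1])) if len(q) == 2
                         else float(np.ptp(pts, axis=0).max()))
            ars.append(1.0)
            continue
        n = mesh.ostium_normal
        # in-plane orthonormal basis
        e1 = np.cross(n, [0.0, 0.0, 1.0])
        if np.linalg.norm(e1) < 1e-8:
            e1 = np.cross(n, [0.0, 1.0, 0.0])
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(n, e1)
        uv = np.stack([q @ e1, q @ e2], axis=1)
        ang = np.argsort(np.arctan2(uv[:, 1], uv[:, 0]))
        uv = uv[ang]
        x, y = uv[:, 0], uv[:, 1]
        areas.append(0.5 * abs(float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))))
        lam = np.linalg.eigvalsh(np.cov(uv.T))
        ars.append(float(np.sqrt(lam[1] / max(lam[0], 1e-30))))
    return float(np.mean(areas)), float(np.mean(ars))
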