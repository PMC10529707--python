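"""The flow-split experiment: one anatomy simulated under four PV flow splits.

Runs {R60, R55, R50*, eqV} on the same moving anatomy and fixed grid with a
shared time step, then compares the four flows with the correlation factors
(per-vein flow rates and 4D velocity fields split into the components
perpendicular/parallel to the mitral plane), per-region kinetic-energy and
residence-time statistics over the averaging window, pairwise z-scores across
the splits, and the one-parameter residence-time model TR = LAV/(alpha LVSV).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .anatomy import AnatomyConfig, make_idealized_la, laa_volume
from .grid import CartesianGrid
from .inflow import build_schedule, eqv_split_fractions
from .metrics import (box_percentiles, correlation_la, correlation_pv,
                      tr_body_model, zscore_across_splits)
from .regions import partition
from .solver import RunResult, SolverConfig, run_case, schedule_peak_velocity

__all__ = ["StudyConfig", "StudyResult", "run_flow_split_study", "load_study_config"]

SCENARIOS_DEFAULT = ("R60", "R55", "R50*", "eqV")
Z_QUANTITIES = (("LAb", "ke_perp"), ("LAb", "ke_par"), ("LAb", "tr"),
                ("LAA", "ke"), ("LAA", "tr"))


@dataclass
class StudyConfig:
    anatomy: AnatomyConfig
    scenarios: tuple = SCENARIOS_DEFAULT
    grid_n: int = 128
    box_half: float = 4.0
    warmup_cycles: int = 2
    cycles: int = 3
    snapshots_per_cycle: int = 32
    coarsen: int = 2
    xi_cut: float = 0.25
    alpha_tr_model: float = 1.4
    solver: SolverConfig = field(default_factory=SolverConfig)
    out_dir: str | None = None
    write_fields: bool = False
    progress: bool = False


@dataclass
class StudyResult:
    correlations: pd.DataFrame   # one row per unordered scenario pair
    region_stats: pd.DataFrame   # one row per scenario x region
    zscores: pd.DataFrame        # one row per (region, quantity)
    timeseries: pd.DataFrame     # per-snapshot region means
    tr_model_cycles: float
    eqv_split: tuple             # (left %, right %)
    manifest: dict
    runs: dict | None = None     # scenario -> RunResult (in-memory only)


def load_study_config(path) -> StudyConfig:
    """Build a StudyConfig from a TOML file.

    Layout: an ``[anatomy]`` table with ``kind`` ("normal"/"impaired"),
    ``dim`` and ``seed`` plus any AnatomyConfig field override, and a
    ``[study]`` table with any StudyConfig field (``scenarios`` as a list).
    """
    import tomllib

    from .anatomy import impaired_anatomy_config, normal_anatomy_config
    with open(path, "rb") as f:
        doc = tomllib.load(f)
    a = dict(doc.get("anatomy", {}))
    kind = a.pop("kind", "normal")
    factory = {"normal": normal_anatomy_config, "impaired": impaired_anatomy_config}[kind]
    anatomy = factory(dim=int(a.pop("dim", 2)), seed=int(a.pop("seed", 0)), **a)
    s = dict(doc.get("study", {}))
    if "scenarios" in s:
        s["scenarios"] = tuple(s["scenarios"])
    return StudyConfig(anatomy=anatomy, **s)


def _region_samples(run: RunResult, masks_by_snap, mv_normal):
    """Pooled per-cell samples over the averaging window, per region."""
    out = {r: {"ke_perp": [], "ke_par": [], "ke": [], "tr": []}
           for r in ("LAPV", "LAb", "LAA")}
    series = []
    n = mv_normal / np.linalg.norm(mv_normal)
    for k, t in enumerate(run.times):
        v = run.u_cell[k].reshape(-1, run.grid.dim)
        tr = run.tr[k].reshape(-1)
        vn = v @ n
        ke_perp = 0.5 * vn ** 2
        ke_par = 0.5 * np.sum((v - vn[:, None] * n) ** 2, axis=1)
        labels = masks_by_snap[k].labels
        for r in out:
            sel = labels == r
            out[r]["ke_perp"].append(ke_perp[sel])
            out[r]["ke_par"].append(ke_par[sel])
            out[r]["ke"].append(ke_perp[sel] + ke_par[sel])
            out[r]["tr"].append(tr[sel])
            series.append({"t": t, "region": r,
                           "mean_tr": float(tr[sel].mean()),
                           "mean_ke": float((ke_perp[sel] + ke_par[sel]).mean())})
    pooled = {r: {q: np.concatenate(v) for q, v in d.items()} for r, d in out.items()}
    return pooled, pd.DataFrame(series)


def run_flow_split_study(config: StudyConfig) -> StudyResult:
    """Run every scenario and assemble the comparison tables.

    All scenarios share the anatomy, grid and time step (chosen from the peak
    boundary velocity across scenarios), so their snapshot times coincide and
    velocity fields are comparable point by point.
    """
    mesh, la_wf, lv_wf, laa_wf = make_idealized_la(config.anatomy)
    n = config.grid_n
    grid = CartesianGrid((n,) * mesh.dim, 2.0 * config.box_half / n,
                         (-config.box_half,) * mesh.dim)
    vmax = schedule_peak_velocity(mesh, lv_wf, config.scenarios)

    runs: dict[str, RunResult] = {}
    for sc in config.scenarios:
        if config.progress:
            print(f"scenario {sc} ...")
        runs[sc] = run_case(mesh, lv_wf, sc, grid, config=config.solver,
                            warmup_cycles=config.warmup_cycles, cycles=config.cycles,
                            coarsen=config.coarsen,
                            snapshots_per_cycle=config.snapshots_per_cycle,
                            vmax=vmax, progress=config.progress)

    first = runs[config.scenarios[0]]
    times = first.times
    cells = first.grid.cell_centers()

    # region masks per snapshot phase (identical across scenarios and cycles)
    phases = np.round(times % mesh.period, 7)
    unique_phases = sorted(set(phases))
    masks_by_phase = {}
    for ph in unique_phases:
        masks_by_phase[ph] = partition(cells, mesh, float(ph), xi_cut=config.xi_cut,
                                       use_mean_mv_plane=True)
    masks_by_snap = [masks_by_phase[ph] for ph in phases]
    mv_normal = masks_by_snap[0].mv_normal

    # per-vein flow-rate waveforms over one cycle (dense) for rho_PV
    tq = np.linspace(0.0, mesh.period, 512, endpoint=False)
    q_by_scenario = {}
    for sc in config.scenarios:
        sched = runs[sc].schedule
        per_vein = {v.name: np.empty_like(tq) for v in mesh.veins}
        for i, t in enumerate(tq):
            q = sched.q_veins(float(t))
            for k, val in q.items():
                per_vein[k][i] = val
        q_by_scenario[sc] = per_vein

    lab_mask = np.stack([m.labels == "LAb" for m in masks_by_snap])
    laa_mask = np.stack([m.labels == "LAA" for m in masks_by_snap])
    flat_u = {sc: runs[sc].u_cell.reshape(len(times), -1, mesh.dim)
              for sc in config.scenarios}

    corr_rows = []
    for a, b in combinations(config.scenarios, 2):
        row = {"pair": f"{a} vs {b}", "i": a, "j": b,
               "rho_pv": correlation_pv(q_by_scenario[a], q_by_scenario[b], tq)}
        row["rho_lab_perp"] = correlation_la(flat_u[a], flat_u[b], lab_mask, times,
                                             normal=mv_normal, component="perp")
        row["rho_lab_par"] = correlation_la(flat_u[a], flat_u[b], lab_mask, times,
                                            normal=mv_normal, component="par")
        row["rho_laa"] = correlation_la(flat_u[a], flat_u[b], laa_mask, times,
                                        component="full")
        corr_rows.append(row)
    correlations = pd.DataFrame(corr_rows)

    stats_rows, ts_frames, pooled_all = [], [], {}
    for sc in config.scenarios:
        pooled, series = _region_samples(runs[sc], masks_by_snap, mv_normal)
        pooled_all[sc] = pooled
        series["scenario"] = sc
        ts_frames.append(series)
        for r, d in pooled.items():
            row = {"scenario": sc, "region": r,
                   "ke_perp_mean": float(d["ke_perp"].mean()),
                   "ke_par_mean": float(d["ke_par"].mean()),
                   "tr_mean": float(d["tr"].mean())}
            row.update({f"tr_p{p}": v for p, v in box_percentiles(d["tr"]).items()})
            stats_rows.append(row)
    region_stats = pd.DataFrame(stats_rows)

    z_rows = []
    for region, quantity in Z_QUANTITIES:
        stats = [(pooled_all[sc][region][quantity].mean(),
                  pooled_all[sc][region][quantity].std(ddof=1))
                 for sc in config.scenarios]
        z_rows.append({"region": region, "quantity": quantity,
                       "z": zscore_across_splits(stats)})
    zscores = pd.DataFrame(z_rows)

    lav = float(np.mean(la_wf.volume(np.linspace(0, mesh.period, 512, endpoint=False))))
    lvsv = float(lv_wf.markers["stroke_volume"])
    tr_model = tr_body_model(lav, lvsv, config.alpha_tr_model) * mesh.period

    areas0 = runs[config.scenarios[0]].schedule.areas(0.0)
    sides = {v.name: v.side for v in mesh.veins}
    eqv = eqv_split_fractions(areas0, sides)

    manifest = {
        "anatomy": {k: v for k, v in asdict(config.anatomy).items()
                    if not isinstance(v, (tuple, list)) or k == "chamber_radii"},
        "scenarios": list(config.scenarios),
        "grid_n": config.grid_n, "box_half": config.box_half,
        "warmup_cycles": config.warmup_cycles, "cycles": config.cycles,
        "vmax_design": vmax,
        "runs": {sc: runs[sc].manifest for sc in config.scenarios},
    }

    result = StudyResult(correlations=correlations, region_stats=region_stats,
                         zscores=zscores, timeseries=pd.concat(ts_frames, ignore_index=True),
                         tr_model_cycles=tr_model / mesh.period, eqv_split=eqv,
                         manifest=manifest, runs=runs)
    if config.out_dir is not None:
        _write_study(result, config, mesh)
    return result


def _write_study(result: StudyResult, config: StudyConfig, mesh):
    from .io import sha256_of, write_manifest, write_mesh_json, write_vtk
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    for name, df in (("correlations", result.correlations),
                     ("region_stats", result.region_stats),
                     ("zscores", result.zscores),
                     ("timeseries", result.timeseries)):
        p = out / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.10g")
        files[name] = sha256_of(p)
    for sc, run in (result.runs or {}).items():
        p = out / f"schedule_{sc.replace('*', 'x')}.csv"
        run.schedule.table().to_csv(p, index=False, float_format="%.10g")
        files[f"schedule_{sc}"] = sha256_of(p)
        if config.write_fields:
            k = len(run.times) - 1
            write_vtk(out / f"fields_{sc.replace('*', 'x')}_final.vtk", run.grid,
                      scalars={"residence_time": run.tr[k]},
                      vectors={"velocity": run.u_cell[k]})
    write_mesh_json(out / "anatomy.json", mesh)
    files["anatomy"] = sha256_of(out / "anatomy.json")
    manifest = dict(result.manifest)
    manifest["files_sha256"] = files
    manifest["tr_model_cycles"] = result.tr_model_cycles
    manifest["eqv_split_left_right"] = list(result.eqv_split)
    write_manifest(out / "manifest.json", manifest)
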