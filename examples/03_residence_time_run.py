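"""A single moving-wall simulation with residence-time transport.

Runs one heartbeat (plus one coarse warm-up beat) of the planar atrium under
the equal-velocity inflow split on a 96^2 grid, then reports the mean blood
residence time per region and writes the final snapshot to VTK.  Takes about
a minute.
"""

from pathlib import Path

import numpy as np

from atriaflow import (CartesianGrid, make_idealized_la, normal_anatomy_config,
                       partition, run_case)
from atriaflow.io import write_vtk
from atriaflow.residence import regional_tr_stats

cfg = normal_anatomy_config(dim=2, seed=1)
mesh, la_wf, lv_wf, laa_wf = make_idealized_la(cfg)
grid = CartesianGrid((96, 96), 8.0 / 96, (-4.0, -4.0))
run = run_case(mesh, lv_wf, "eqV", grid, warmup_cycles=1, cycles=1,
               snapshots_per_cycle=8, progress=True)

k = len(run.times) - 1
masks = partition(run.grid.cell_centers(), mesh, float(run.times[k] % mesh.period))
stats = regional_tr_stats(run.tr[k], masks)
print(f"\nafter {run.times[k]:.1f} s of simulated flow:")
for region, s in stats.items():
    print(f"  {region:5s}: mean TR {s['mean']:.2f} s, median {s[50]:.2f}, "
          f"9-91% range [{s[9]:.2f}, {s[91]:.2f}]")
print("Residence time measures how long blood has been inside the chamber; "
      "the appendage (LAA) retains blood longer than the conduit-like body "
      "already after two beats (values keep rising until the flow is "
      "periodic, typically ~10 beats).")

out = Path("scratch/run_demo")
out.mkdir(parents=True, exist_ok=True)
write_vtk(out / "final.vtk", run.grid,
          scalars={"residence_time": run.tr[k]}, vectors={"velocity": run.u_cell[k]})
speed = np.linalg.norm(run.u_cell[k], axis=-1)
print(f"peak speed {speed.max():.1f} cm/s; snapshot written to {out}/final.vtk")
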