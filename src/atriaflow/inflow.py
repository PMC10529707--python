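"""Pulmonary-vein inflow and mitral outflow schedules.

The chamber is fed by the pulmonary veins and drained through the mitral
valve.  With no mitral regurgitation, the transmitral flow rate is the
positive part of dV_LV/dt, and mass conservation of the (moving-wall) atrium
fixes the *total* PV inflow:

    Q_PV(t) = dV_LA/dt + Q_MV(t).

How Q_PV is split across the individual veins is the study parameter.  Four
scenarios are supported:

* ``R60`` / ``R55`` — 60% / 55% of Q_PV through the right veins, the rest
  through the left, distributed within each side proportionally to the
  instantaneous cap areas (the same velocity at each of a side's inlets);
* ``R50*`` — the same flow rate through every vein, Q_i = Q_PV / n;
* ``eqV`` — the same velocity through every vein, Q_i = Q_PV * A_i / A_PV.

All scenarios conserve mass exactly: sum_i Q_i(t) = Q_PV(t) at every instant,
including during flow reversal (negative Q_PV propagates its sign to every
vein).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anatomy import LASurfaceMesh, evaluate_mesh, volume_rate
from .waveforms import VolumeWaveform

__all__ = [
    "FlowSplitScenario",
    "SCENARIOS",
    "MitralSchedule",
    "InflowSchedule",
    "mitral_flow",
    "total_pv_inflow",
    "split_flow",
    "eqv_split_fractions",
    "build_schedule",
]


@dataclass(frozen=True)
class FlowSplitScenario:
    """One of the four pulmonary-vein flow-split conditions."""

    name: str
    right_fraction: float | None  # None for R50* and eqV

    def split(self, q_pv: float, areas: dict, sides: dict) -> dict:
        """Distribute the instantaneous total inflow across veins (ml/s)."""
        names = list(areas)
        a = np.array([areas[k] for k in names], dtype=float)
        if np.any(a <= 0):
            bad = names[int(np.argmin(a))]
            raise ValueError(f"nonpositive inlet area for {bad!r}")
        if self.name == "R50*":
            q = np.full(len(names), q_pv / len(names))
        elif self.name == "eqV":
            q = q_pv * a / a.sum()
        else:
            fr = self.right_fraction
            right = np.array([sides[k] == "R" for k in names])
            if not right.any() or right.all():
                raise ValueError("side-fraction splits need veins on both sides")
            q = np.empty(len(names))
            q[right] = fr * q_pv * a[right] / a[right].sum()
            q[~right] = (1.0 - fr) * q_pv * a[~right] / a[~right].sum()
        return dict(zip(names, q))


SCENARIOS = {
    "R60": FlowSplitScenario("R60", 0.60),
    "R55": FlowSplitScenario("R55", 0.55),
    "R50*": FlowSplitScenario("R50*", None),
    "eqV": FlowSplitScenario("eqV", None),
}


@dataclass
class MitralSchedule:
    """Transmitral flow: Q_MV(t) = (dV_LV/dt)^+ and the valve state."""

    lv: VolumeWaveform

    @property
    def period(self) -> float:
        return self.lv.period

    def q_mv(self, t):
        return np.maximum(self.lv.rate(t), 0.0)

    def mv_open(self, t):
        return self.lv.rate(t) > 0.0


def mitral_flow(lv: VolumeWaveform) -> MitralSchedule:
    """Mitral outflow from the LV volume waveform (no regurgitation).

    The valve is open exactly where dV_LV/dt > 0; the cycle integral of Q_MV
    equals the LV stroke volume.
    """
    return MitralSchedule(lv)


def total_pv_inflow(la: VolumeWaveform, mitral: MitralSchedule):
    """Total PV inflow from chamber mass conservation.

    Returns a callable Q_PV(t) = dV_LA/dt + Q_MV(t).  Over one cycle its
    integral equals the integral of Q_MV (the LA volume is periodic).
    """
    if abs(la.period - mitral.period) > 1e-12 * la.period:
        raise ValueError(f"mismatched periods: LA {la.period} s vs LV {mitral.period} s")

    def q_pv(t):
        return la.rate(t) + mitral.q_mv(t)

    return q_pv


def split_flow(q_pv: float, scenario: FlowSplitScenario, areas: dict, sides: dict) -> dict:
    """Instantaneous per-vein flow rates under the given scenario."""
    return scenario.split(q_pv, areas, sides)


def eqv_split_fractions(areas: dict, sides: dict) -> tuple[float, float]:
    """(left%, right%) of the equal-velocity split, from the cap areas."""
    tot = sum(areas.values())
    left = 100.0 * sum(a for k, a in areas.items() if sides[k] == "L") / tot
    return left, 100.0 - left


class InflowSchedule:
    """Full boundary-condition schedule for one anatomy x one scenario.

    Provides per-vein flow rates Q_i(t), target inlet velocity vectors
    v_t = (Q_i / A_i) n (with n the inward cap normal), the mitral flow and
    valve state.  The LA volume rate is taken exactly from the Fourier mesh so
    the schedule is mass-consistent with the wall motion the solver imposes.
    """

    def __init__(self, mesh: LASurfaceMesh, lv: VolumeWaveform,
                 scenario: FlowSplitScenario, areas_instantaneous: bool = True):
        self.mesh = mesh
        self.scenario = scenario
        self.mitral = mitral_flow(lv)
        self.period = mesh.period
        self.sides = {v.name: v.side for v in mesh.veins}
        self._areas_instantaneous = areas_instantaneous
        self._static_frame = evaluate_mesh(mesh, 0.0)
        # caps whose vertices carry no harmonics are static: their areas are
        # time-independent and need not be re-measured
        cap_verts = np.unique(np.concatenate(
            [mesh.patch_faces(v.name).ravel() for v in mesh.veins]))
        self._caps_static = bool(np.abs(mesh.coeffs[cap_verts, :, 1:]).max() < 1e-12)

    def areas(self, t: float) -> dict:
        if self._areas_instantaneous and not self._caps_static:
            frame = evaluate_mesh(self.mesh, t)
        else:
            frame = self._static_frame
        return {v.name: frame.patch_area[v.name] for v in self.mesh.veins}

    def q_pv(self, t: float) -> float:
        return volume_rate(self.mesh, t) + float(self.mitral.q_mv(t))

    def q_veins(self, t: float) -> dict:
        return self.scenario.split(self.q_pv(t), self.areas(t), self.sides)

    def target_velocities(self, t: float) -> dict:
        """Per-vein target velocity vectors at the inlet planes (cm/s)."""
        areas = self.areas(t)
        q = self.scenario.split(self.q_pv(t), areas, self.sides)
        out = {}
        for v in self.mesh.veins:
            n_in = -v.d  # inward normal of the cap
            out[v.name] = (q[v.name] / areas[v.name]) * n_in
        return out

    def table(self, n: int = 256):
        """Sampled schedule over one period as a pandas DataFrame."""
        import pandas as pd
        t = np.linspace(0.0, self.period, n, endpoint=False)
        rows = []
        for tk in t:
            q = self.q_veins(tk)
            row = {"t": tk, "QPV": self.q_pv(tk), "QMV": float(self.mitral.q_mv(tk)),
                   "mv_open": bool(self.mitral.mv_open(tk))}
            row.update({f"Q_{k}": v for k, v in q.items()})
            rows.append(row)
        return pd.DataFrame(rows)


def build_schedule(mesh: LASurfaceMesh, lv: VolumeWaveform, scenario) -> InflowSchedule:
    if isinstance(scenario, str):
        scenario = SCENARIOS[scenario]
    return InflowSchedule(mesh, lv, scenario)
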