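"""Mass-conservation inflow, mitral schedule and the four flow-split rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atriaflow import (SCENARIOS, build_schedule, eqv_split_fractions,
                       mitral_flow, split_flow, total_pv_inflow, volume_rate)
from atriaflow.waveforms import FourierWaveform, lv_volume_waveform

FOUR_SIDES = {"RS": "R", "RI": "R", "LS": "L", "LI": "L"}


def test_mitral_flow_cosine_ventricle():
    """V_LV = 100 - 30 cos(2 pi t): filling on (0, 1/2), Q_MV = 60 pi sin."""
    lv = FourierWaveform(100.0, np.array([-30.0]), np.array([0.0]), 1.0)
    sched = mitral_flow(lv)
    t = np.linspace(0.01, 0.49, 50)
    assert np.allclose(sched.q_mv(t), 60 * np.pi * np.sin(2 * np.pi * t), atol=1e-10)
    assert sched.mv_open(t).all()
    t2 = np.linspace(0.51, 0.99, 50)
    assert np.allclose(sched.q_mv(t2), 0.0)
    assert not sched.mv_open(t2).any()


def test_mitral_flow_constant_ventricle_never_opens():
    lv = FourierWaveform(120.0, np.array([0.0]), np.array([0.0]), 1.0)
    sched = mitral_flow(lv)
    t = np.linspace(0, 1, 100)
    assert np.allclose(sched.q_mv(t), 0.0)
    assert not sched.mv_open(t).any()


def test_mitral_cycle_integral_equals_stroke_volume():
    lv = lv_volume_waveform(160.0, 72.2, e_fraction=0.65)
    sched = mitral_flow(lv)
    t = np.linspace(0, 1, 32768, endpoint=False)
    vol = float(np.sum(sched.q_mv(t))) / len(t)
    assert vol == pytest.approx(72.2, abs=0.5)


def test_total_pv_inflow_pure_reservoir():
    """V_LA = 100 + 10 sin(2 pi t), Q_MV = 0 -> Q_PV = 20 pi cos(2 pi t)."""
    la = FourierWaveform(100.0, np.array([0.0]), np.array([10.0]), 1.0)
    lv = FourierWaveform(120.0, np.array([0.0]), np.array([0.0]), 1.0)
    q_pv = total_pv_inflow(la, mitral_flow(lv))
    t = np.linspace(0, 1, 64)
    assert np.allclose(q_pv(t), 20 * np.pi * np.cos(2 * np.pi * t), atol=1e-10)


def test_total_pv_inflow_conduit_limit():
    """Static LA: the PV inflow is exactly the mitral outflow."""
    la = FourierWaveform(100.0, np.array([0.0]), np.array([0.0]), 1.0)
    lv = lv_volume_waveform(160.0, 70.0)
    sched = mitral_flow(lv)
    q_pv = total_pv_inflow(la, sched)
    t = np.linspace(0, 1, 200)
    assert np.allclose(q_pv(t), sched.q_mv(t), atol=1e-12)


def test_pv_cycle_volume_equals_stroke_volume():
    from atriaflow.waveforms import la_volume_waveform
    la = la_volume_waveform(59.6, 108.0, 94.3)
    lv = lv_volume_waveform(160.0, 72.2)
    q_pv = total_pv_inflow(la, mitral_flow(lv))
    t = np.linspace(0, 1, 32768, endpoint=False)
    assert float(np.mean(q_pv(t))) == pytest.approx(72.2, abs=0.5)


def test_period_mismatch_rejected():
    la = FourierWaveform(100.0, np.array([1.0]), np.array([0.0]), 1.0)
    lv = FourierWaveform(120.0, np.array([1.0]), np.array([0.0]), 0.8)
    with pytest.raises(ValueError, match="period"):
        total_pv_inflow(la, mitral_flow(lv))


# ---------------------------------------------------------------------------
# flow splits
# ---------------------------------------------------------------------------

AREAS = {"RS": 2.0, "RI": 1.0, "LS": 2.0, "LI": 1.0}


def test_split_r60_distributes_by_side_and_area():
    q = split_flow(100.0, SCENARIOS["R60"], AREAS, FOUR_SIDES)
    assert q["RS"] == pytest.approx(40.0)
    assert q["RI"] == pytest.approx(20.0)
    assert q["LS"] == pytest.approx(26.0 + 2.0 / 3.0)
    assert q["LI"] == pytest.approx(13.0 + 1.0 / 3.0)
    # same velocity at each of a side's inlets
    assert q["RS"] / AREAS["RS"] == pytest.approx(q["RI"] / AREAS["RI"])


def test_split_eqv_is_equal_velocity():
    q = split_flow(100.0, SCENARIOS["eqV"], AREAS, FOUR_SIDES)
    assert q["RS"] == pytest.approx(100.0 / 3.0)
    vels = [q[k] / AREAS[k] for k in AREAS]
    assert np.ptp(vels) < 1e-12
    assert vels[0] == pytest.approx(100.0 / 6.0)


def test_equal_areas_make_r50_and_eqv_coincide():
    areas = {k: 1.0 for k in FOUR_SIDES}
    q1 = split_flow(100.0, SCENARIOS["R50*"], areas, FOUR_SIDES)
    q2 = split_flow(100.0, SCENARIOS["eqV"], areas, FOUR_SIDES)
    for k in areas:
        assert q1[k] == pytest.approx(25.0) == pytest.approx(q2[k])


def test_nonpositive_area_rejected():
    bad = dict(AREAS, RI=0.0)
    with pytest.raises(ValueError, match="area"):
        split_flow(10.0, SCENARIOS["eqV"], bad, FOUR_SIDES)


@pytest.mark.parametrize("areas,expected_left", [
    ({"RS": 2, "RI": 1, "LS": 2, "LI": 1}, 50.0),
    ({"RS": 3, "RI": 3, "LS": 2, "LI": 2}, 40.0),
    ({"RS": 1, "RI": 1, "LS": 1, "LI": 0}, 100.0 / 3.0),  # degenerate 3-vein case
])
def test_eqv_split_fractions(areas, expected_left):
    left, right = eqv_split_fractions(areas, FOUR_SIDES)
    assert left == pytest.approx(expected_left)
    assert right == pytest.approx(100.0 - expected_left)


@settings(max_examples=60, deadline=None)
@given(q_pv=st.floats(-200, 200),
       a=st.tuples(*(st.floats(0.2, 4.0) for _ in range(4))))
def test_conservation_and_sign_propagation(q_pv, a):
    """Every scenario conserves the total inflow exactly and propagates the
    sign of Q_PV (reverse flow) to all veins."""
    areas = dict(zip(FOUR_SIDES, a))
    for sc in SCENARIOS.values():
        q = split_flow(q_pv, sc, areas, FOUR_SIDES)
        assert sum(q.values()) == pytest.approx(q_pv, abs=1e-12 * max(1, abs(q_pv)))
        if abs(q_pv) > 1e-9:
            assert all(np.sign(v) == np.sign(q_pv) for v in q.values())


# ---------------------------------------------------------------------------
# schedules on the built anatomy
# ---------------------------------------------------------------------------

def test_schedule_mass_consistency(anatomy_2d):
    mesh, la_wf, lv_wf, laa_wf, cfg = anatomy_2d
    sched = build_schedule(mesh, lv_wf, "R55")
    for t in (0.05, 0.31, 0.52, 0.86):
        q = sched.q_veins(t)
        assert sum(q.values()) == pytest.approx(sched.q_pv(t), abs=1e-10)
        assert sched.q_pv(t) == pytest.approx(volume_rate(mesh, t)
                                              + sched.mitral.q_mv(t), abs=1e-10)


def test_symmetric_anatomy_r50_equals_eqv(anatomy_2d):
    """With equal inlet areas the even-rate and equal-velocity splits coincide."""
    from atriaflow import TubeSpec, make_idealized_la, normal_anatomy_config
    cfg = normal_anatomy_config(dim=2, seed=3)
    r = 0.35
    cfg.veins = (
        TubeSpec("PV_R", "pv", tuple(cfg.veins[0].d), r, cfg.veins[0].length, side="R"),
        TubeSpec("PV_L", "pv", tuple(cfg.veins[1].d), r, cfg.veins[1].length, side="L"),
    )
    mesh, la_wf, lv_wf, _ = make_idealized_la(cfg)
    s_even = build_schedule(mesh, lv_wf, "R50*")
    s_eqv = build_schedule(mesh, lv_wf, "eqV")
    for t in (0.1, 0.5, 0.9):
        qa, qb = s_even.q_veins(t), s_eqv.q_veins(t)
        for k in qa:
            assert qa[k] == pytest.approx(qb[k], abs=1e-9)


def test_target_velocity_along_inward_normal(anatomy_2d):
    mesh, la_wf, lv_wf, laa_wf, cfg = anatomy_2d
    sched = build_schedule(mesh, lv_wf, "eqV")
    vt = sched.target_velocities(0.3)
    for v in mesh.veins:
        direction = vt[v.name] / np.linalg.norm(vt[v.name])
        assert direction @ (-v.d) == pytest.approx(1.0, abs=1e-12)
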