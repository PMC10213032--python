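"""Growth-engine behavior: conservation, branching bookkeeping, geometry."""

import math

import numpy as np
import pytest

import mycelia as m
from mycelia.laws import elongation_velocity
from mycelia.simulate import Simulation


def _no_branch_config(seed=0, t_end=6.0, dt=0.1, n_init=2):
    cfg = m.reference_config(seed=seed, t_end_h=t_end)
    cfg.apical_enabled = False
    cfg.lateral_enabled = False
    cfg.dt_h = dt
    cfg.germination.n_initial_hyphae = n_init
    return cfg


def test_length_conservation_without_branching():
    """With branching disabled, total length equals n_init * ∫ v dt."""
    cfg = _no_branch_config(t_end=6.0)
    traj = m.run(cfg)
    steps = np.arange(int(round(cfg.t_end_h / cfg.dt_h)))
    discrete = sum(elongation_velocity((s + 0.5) * cfg.dt_h, cfg.germination)
                   * cfg.dt_h for s in steps)
    total = m.total_length(traj.final_graph)
    assert total == pytest.approx(2 * discrete, rel=1e-6)
    # curvature does not create or destroy arclength: matches the integral
    from mycelia.laws import cumulative_growth
    assert total == pytest.approx(2 * cumulative_growth(6.0, cfg.germination),
                                  rel=0.01)


def test_apex_count_nondecreasing_and_event_bookkeeping(ref_traj):
    n1 = ref_traj.n1
    assert np.all(np.diff(n1) >= 0)
    # every branching adds exactly one apex
    n_init = ref_traj.config.germination.n_initial_hyphae
    t_last = ref_traj.times[-1]
    n_events = sum(1 for ev in ref_traj.events if ev.time_h <= t_last + 1e-9)
    assert n1[-1] == n_init + n_events


def test_snapshot_cadence_matches_config(ref_traj):
    cad = ref_traj.config.snapshot_cadence_min / 60.0
    assert np.allclose(np.diff(ref_traj.times), cad, atol=1e-9)


def test_inter_apical_spacings_respect_dominance(ref_traj):
    spac = m.inter_apical_lengths(ref_traj)
    assert spac.size > 100
    assert spac.min() >= 180.0
    # completed spacings in a growing population are censored downward,
    # never upward of the law's mean
    assert spac.mean() < 180.0 + 1.0 / (10.4e-3 * math.log(2)) + 10.0


def test_lateral_events_never_inside_dominance_zone(ref_traj):
    lat = [ev for ev in ref_traj.events if ev.type == "lateral"]
    assert len(lat) > 20
    assert min(ev.L_lat_um for ev in lat) >= 480.0
    for ev in lat[:50]:
        assert ev.L_lat_um <= ev.L_hypha_um + 1e-6


def test_no_lateral_variant_has_no_lateral_events():
    traj = m.run(m.no_lateral_config(seed=2, t_end_h=12.0))
    assert all(ev.type == "apical" for ev in traj.events)


def test_symmetric_curvature_gives_zero_mean_turning(ref_traj):
    """With a = b the average cross product of successive velocity vectors
    of the apexes vanishes."""
    crosses = []
    for h in ref_traj.hyphae:
        p = np.column_stack([h.px, h.py])
        if len(p) < 3:
            continue
        v = np.diff(p, axis=0)
        crosses.extend(v[:-1, 0] * v[1:, 1] - v[:-1, 1] * v[1:, 0])
    crosses = np.asarray(crosses)
    assert crosses.size > 1000
    se = crosses.std() / math.sqrt(crosses.size)
    assert abs(crosses.mean()) < 3 * se


@pytest.mark.parametrize("dt", [0.1, 0.02])
def test_curvature_statistics_are_dt_invariant(dt):
    """Tortuosity is governed by the per-step_length turn law, not by the
    integration step."""
    alphas = []
    for seed in range(3):
        cfg = _no_branch_config(seed=seed, t_end=8.0, dt=dt, n_init=2)
        traj = m.run(cfg)
        alphas.append(m.tortuosity(traj.final_graph).alpha)
    assert 0.015 < np.mean(alphas) < 0.08


def test_simulated_tortuosity_in_measured_range(ref_traj):
    # arc-chord tortuosity of a grown thallus, calibration target ≈ 0.038
    alpha = m.tortuosity(ref_traj.graph(12.0)).alpha
    assert 0.02 < alpha < 0.06


def test_step_validation():
    cfg = _no_branch_config(t_end=1.0)
    sim = Simulation(cfg)
    with pytest.raises(ValueError):
        sim.step(-0.1)
    for _ in range(10):
        sim.step()
    with pytest.raises(ValueError):
        for _ in range(10):
            sim.step()


def test_intermediate_graph_is_valid(ref_traj):
    g = ref_traj.graph(7.0)
    g.validate()
    assert g.snapshot_time == 7.0
    assert np.all(g.birth_h <= 7.0 + 1e-9)
    # the graph tip count matches the number of hyphae alive at that time
    # (each germ tube also contributes its degree-1 base vertex)
    c = m.classify_vertices(g, include_crossings=False)
    n_init = ref_traj.config.germination.n_initial_hyphae
    alive = n_init + sum(1 for ev in ref_traj.events if ev.time_h <= 7.0)
    assert c.v1 + c.v1l - n_init == alive


def test_determinism_same_seed_same_trajectory():
    a = m.run(m.reference_config(seed=11, t_end_h=8.0))
    b = m.run(m.reference_config(seed=11, t_end_h=8.0))
    assert len(a.events) == len(b.events)
    assert np.array_equal(a.apex_xy[-1], b.apex_xy[-1])


def test_operating_branch_makes_wider_angle_than_continuation():
    """The operating daughter deviates ~70 deg from the mother projection
    and the exploratory continuation ~20 deg, on opposite sides."""
    cfg = m.reference_config(seed=4, t_end_h=7.0)
    cfg.lateral_enabled = False
    cfg.angle_jitter_deg = 0.0
    for k in cfg.curvature:
        cfg.curvature[k].theta0_rad = 1e-6  # effectively straight growth
    traj = m.run(cfg)
    ops = sorted((h for h in traj.hyphae if h.btype == "operating"),
                 key=lambda h: h.birth_h)
    assert ops, "no apical branching happened"

    def wrap(a):
        return (a + math.pi) % (2 * math.pi) - math.pi

    checked = 0
    for child in ops[:5]:
        mother = traj.hyphae[child.parent]
        n_ev = sum(1 for ev in traj.events
                   if ev.type == "apical" and ev.hypha_id == mother.hid)
        if mother.btype != "germination" or n_ev != 1:
            continue
        # germination hyphae grow straight here, so the pre-branch heading
        # is the direction of the mother's first segment
        pre = math.atan2(mother.py[1] - mother.py[0], mother.px[1] - mother.px[0])
        d_child = wrap(child.heading - pre) if len(child.px) == 1 else wrap(
            math.atan2(child.py[1] - child.py[0], child.px[1] - child.px[0]) - pre)
        d_mother_after = wrap(mother.heading - pre)
        assert abs(abs(d_child) - math.radians(70)) < math.radians(2)
        assert abs(abs(d_mother_after) - math.radians(20)) < math.radians(2)
        assert np.sign(d_child) == -np.sign(d_mother_after)
        checked += 1
    assert checked >= 1
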