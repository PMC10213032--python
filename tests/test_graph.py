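"""Spatial-graph model: vertex classification, crossings, tortuosity."""

import math

import numpy as np
import pytest

import mycelia as m
from mycelia.graph import DegenerateGraphError, MalformedGraphError
from mycelia.io import FixtureSpec, generate_fixture


def _graph(nodes, edges, t=10.0):
    return m.NetworkGraph.from_records(nodes, edges, snapshot_time=t)


def test_single_filament_both_ends_are_tips():
    g = generate_fixture(FixtureSpec("toy_graph", {"shape": "filament"}))
    c = m.classify_vertices(g)
    assert (c.v1, c.v3, c.v3i, c.internal) == (2, 0, 0, 0)
    with pytest.raises(DegenerateGraphError):
        m.one_body_ratio(c)


def test_y_shaped_apical_branching_counts_and_ratio():
    g = generate_fixture(FixtureSpec("toy_graph", {"shape": "Y"}))
    c = m.classify_vertices(g)
    assert (c.v1, c.v3, c.v3l, c.v3i) == (3, 1, 0, 0)
    assert m.one_body_ratio(c) == pytest.approx(3.0)


def test_two_disjoint_crossing_filaments():
    g = generate_fixture(FixtureSpec("toy_graph", {"shape": "X"}))
    c = m.classify_vertices(g)
    assert c.v1 == 4 and c.v3i == 1
    assert m.one_body_ratio(c) == pytest.approx(4.0)


@pytest.mark.parametrize(
    "nodes,edges,expected",
    [
        # plain X crossing
        ([(0, -1, -1), (1, 1, 1), (2, -1, 1), (3, 1, -1)],
         [(0, 1), (2, 3)], 1),
        # parallel segments never cross
        ([(0, 0, 0), (1, 10, 0), (2, 0, 1), (3, 10, 1)],
         [(0, 1), (2, 3)], 0),
        # endpoint touching a segment interior is a T junction, not a crossing
        ([(0, 0, -1), (1, 0, 1), (2, 0, 0), (3, 5, 0)],
         [(0, 1), (2, 3)], 0),
        # collinear overlap is not transversal
        ([(0, 0, 0), (1, 10, 0), (2, 5, 0), (3, 15, 0)],
         [(0, 1), (2, 3)], 0),
        # three mutually crossing segments
        ([(0, 0, 1), (1, 10, 1), (2, 2, 0), (3, 6, 3), (4, 8, 0), (5, 4, 3)],
         [(0, 1), (2, 3), (4, 5)], 3),
    ],
)
def test_crossing_counts(nodes, edges, expected):
    assert m.count_crossings(_graph(nodes, edges)) == expected


def _brute_force_crossings(graph):
    """O(n^2) orientation-test oracle for transversal crossings."""
    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    seg = graph.segment_coords()
    n = len(seg)
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            ea, eb = graph.edges[i], graph.edges[j]
            if len(set(ea.tolist()) & set(eb.tolist())):
                continue
            p1, p2 = seg[i]
            p3, p4 = seg[j]
            d1 = cross(p3, p4, p1)
            d2 = cross(p3, p4, p2)
            d3 = cross(p1, p2, p3)
            d4 = cross(p1, p2, p4)
            if d1 * d2 < 0 and d3 * d4 < 0:
                total += 1
    return total


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_crossings_match_brute_force_on_random_segments(seed):
    rng = np.random.default_rng(seed)
    n = 80
    pts = rng.uniform(0, 100, size=(2 * n, 2))
    nodes = [(i, x, y) for i, (x, y) in enumerate(pts)]
    edges = [(2 * k, 2 * k + 1) for k in range(n)]
    g = _graph(nodes, edges)
    assert m.count_crossings(g) == _brute_force_crossings(g)


def test_crossings_match_brute_force_on_simulated_thallus(ref_traj):
    g = ref_traj.graph(8.0)
    assert g.n_edges <= 2000
    assert m.count_crossings(g) == _brute_force_crossings(g)


def test_tortuosity_straight_chain_is_zero():
    nodes = [(i, 10.0 * i, 0.0) for i in range(5)]
    edges = [(i, i + 1) for i in range(4)]
    assert m.tortuosity(_graph(nodes, edges)).alpha == pytest.approx(0.0, abs=1e-12)


def test_tortuosity_l_shaped_chain_hand_value():
    g = _graph([(0, 0, 0), (1, 1, 0), (2, 1, 1)], [(0, 1), (1, 2)])
    res = m.tortuosity(g)
    assert res.l_tot_um == pytest.approx(2.0)
    assert res.l_pruned_um == pytest.approx(math.sqrt(2.0))
    assert res.alpha == pytest.approx((2 - math.sqrt(2)) / (2 + math.sqrt(2)), abs=1e-9)
    assert res.alpha == pytest.approx(0.17157, abs=1e-4)


def test_tortuosity_invariant_under_rigid_motion(ref_traj):
    g = ref_traj.graph(9.0)
    a0 = m.tortuosity(g).alpha
    th = math.radians(61.3)
    rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    g2 = m.NetworkGraph(
        node_ids=g.node_ids, xy=g.xy @ rot.T + np.array([123.0, -45.0]),
        birth_h=g.birth_h, provenance=g.provenance, edges=g.edges,
        branch_type=g.branch_type, snapshot_time=g.snapshot_time,
    )
    assert m.tortuosity(g2).alpha == pytest.approx(a0, abs=1e-9)


def test_empty_graph_measures_error():
    g = m.NetworkGraph.from_records([], [])
    with pytest.raises(DegenerateGraphError):
        m.total_length(g)
    with pytest.raises(DegenerateGraphError):
        m.tortuosity(g)


def test_degree_four_node_is_malformed():
    nodes = [(0, 0, 0), (1, 1, 0), (2, -1, 0), (3, 0, 1), (4, 0, -1)]
    edges = [(0, 1), (0, 2), (0, 3), (0, 4)]
    with pytest.raises(MalformedGraphError):
        m.classify_vertices(_graph(nodes, edges))


def test_binary_tree_tip_junction_identity():
    """Apical-only growth from one germ tube: #V1 = #V3 + 2."""
    cfg = m.reference_config(seed=5, t_end_h=11.0)
    cfg.lateral_enabled = False
    cfg.germination.n_initial_hyphae = 1
    traj = m.run(cfg)
    c = m.classify_vertices(traj.graph(11.0), include_crossings=False)
    assert c.v3 >= 3
    assert c.v1 == c.v3 + 2
    assert c.v1l == 0 and c.v3l == 0


def test_full_thallus_tip_identity_and_ratio(ref_traj):
    g = ref_traj.final_graph
    c = m.classify_vertices(g)
    n_init = ref_traj.config.germination.n_initial_hyphae
    # every branching adds one tip; each germ tube contributes base + apex
    assert c.v1 + c.v1l == c.v3 + c.v3l + 2 * n_init
    ratio_with = m.one_body_ratio(c, include_crossings=True)
    ratio_without = m.one_body_ratio(c, include_crossings=False)
    assert ratio_with < ratio_without
    assert 0 < ratio_with < ratio_without <= c.one_body


def test_counts_sum_to_node_count(ref_traj):
    g = ref_traj.graph(10.0)
    c = m.classify_vertices(g)
    assert c.total() - c.v3i == g.n_nodes


def test_missing_provenance_lumps_subclasses():
    nodes = [(0, 0.0, 0.0), (1, 0.0, 100.0), (2, -60.0, 180.0), (3, 60.0, 180.0)]
    edges = [(0, 1), (1, 2), (1, 3)]
    c = m.classify_vertices(_graph(nodes, edges))
    assert not c.subclasses_known
    assert c.v1 == 3 and c.v1l == 0 and c.v3 == 1 and c.v3l == 0
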