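import math

import numpy as np
import pandas as pd
import pytest

import oracles
from frnetsim import fr_network
from frnetsim.fr_network import (
    MIGraph, build_mi_graph, characteristic_path_length, feature_vector,
    global_efficiency, graph_radius, local_efficiency, spatial_frnet,
    temporal_frnet_a, temporal_frnet_b,
)

from conftest import make_patient


def random_mi_graph(rng, n=None, p_edge=0.7):
    n = n or int(rng.integers(3, 9))
    a = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    vals = rng.uniform(0.05, 2.0, len(iu[0]))
    vals[rng.random(len(vals)) > p_edge] = 0.0
    a[iu] = vals
    a += a.T
    return MIGraph(node_ids=[f"c{i}" for i in range(n)], adjacency=a)


def lengths_list(g):
    return [[float(v) for v in row] for row in g.lengths]


# ---------------------------------------------------------------------------
# structure
# ---------------------------------------------------------------------------

def test_migraph_invariants():
    g = random_mi_graph(np.random.default_rng(0), n=5)
    assert np.allclose(g.adjacency, g.adjacency.T)
    assert np.all(np.diag(g.adjacency) == 0)
    L = g.lengths
    mask = g.adjacency > 0
    assert np.allclose(L[mask], 1.0 / g.adjacency[mask])
    assert np.all(np.isinf(L[~mask & ~np.eye(5, dtype=bool)]))
    with pytest.raises(ValueError, match="symmetric"):
        MIGraph(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))
    with pytest.raises(ValueError, match="nonnegative"):
        MIGraph(["a", "b"], np.array([[0.0, -1.0], [-1.0, 0.0]]))


def test_edge_frame_roundtrip():
    g = random_mi_graph(np.random.default_rng(1), n=6)
    df = g.to_edge_frame()
    for _, r in df.iterrows():
        i, j = g.node_ids.index(r.node_a), g.node_ids.index(r.node_b)
        assert r.mi_bits == g.adjacency[i, j]
    nxg = g.to_networkx()
    assert set(nxg.nodes) == set(g.node_ids)
    assert nxg.number_of_edges() == len(df)


# ---------------------------------------------------------------------------
# metrics vs brute-force oracles
# ---------------------------------------------------------------------------

def test_graph_metrics_match_bruteforce_oracles():
    """LE, characteristic path length and global efficiency agree with
    independently coded Floyd-Warshall oracles on 100 random graphs."""
    rng = np.random.default_rng(42)
    for _ in range(100):
        g = random_mi_graph(rng)
        L = lengths_list(g)
        adj = [[float(v) for v in row] for row in g.adjacency]
        n = g.n_nodes
        for i in range(n):
            assert local_efficiency(g, i) == pytest.approx(
                oracles.local_efficiency(adj, i), abs=1e-10)
        sub = list(rng.choice(n, size=rng.integers(2, n + 1), replace=False))
        ids = [g.node_ids[i] for i in sub]
        cpl, n_inf = characteristic_path_length(g, ids)
        ocpl, on_inf = oracles.char_path_length(L, sub)
        assert n_inf == on_inf
        if ocpl is None:
            assert cpl is None
        else:
            assert cpl == pytest.approx(ocpl, abs=1e-10)
        ge = global_efficiency(g, ids)
        assert ge == pytest.approx(oracles.global_efficiency(L, sub), abs=1e-10)


def test_local_efficiency_conventions():
    # complete graph with equal weights: normalization forces LE = 1
    n = 5
    a = np.full((n, n), 0.3)
    np.fill_diagonal(a, 0.0)
    g = MIGraph([f"c{i}" for i in range(n)], a)
    for i in range(n):
        assert local_efficiency(g, i) == pytest.approx(1.0)
    # isolated node has LE 0
    a2 = np.zeros((3, 3))
    a2[0, 1] = a2[1, 0] = 1.0
    g2 = MIGraph(["a", "b", "c"], a2)
    assert local_efficiency(g2, "c") == 0.0
    assert local_efficiency(g2, "a") == 0.0  # single neighbor


def test_characteristic_path_length_line_graph():
    """3-node line with unit lengths: finite-pair mean is 4/3."""
    a = np.zeros((3, 3))
    a[0, 1] = a[1, 0] = 1.0
    a[1, 2] = a[2, 1] = 1.0
    g = MIGraph(["a", "b", "c"], a)
    cpl, n_inf = characteristic_path_length(g)
    assert cpl == pytest.approx(4.0 / 3.0)
    assert n_inf == 0
    # two nodes with MI 0.5: length 2
    a2 = np.array([[0.0, 0.5], [0.5, 0.0]])
    g2 = MIGraph(["a", "b"], a2)
    assert characteristic_path_length(g2)[0] == pytest.approx(2.0)
    assert characteristic_path_length(g2, ["a"])[0] is None


def test_global_efficiency_direct_edge_is_mi():
    g = MIGraph(["a", "b"], np.array([[0.0, 0.5], [0.5, 0.0]]))
    assert global_efficiency(g) == pytest.approx(0.5)
    g2 = MIGraph(["a", "b"], np.zeros((2, 2)))
    assert global_efficiency(g2) == 0.0
    assert global_efficiency(g, ["a"]) is None


# ---------------------------------------------------------------------------
# rate-distance radii
# ---------------------------------------------------------------------------

def rates_frame(ids, fr350):
    return pd.DataFrame(
        {"fr350": fr350, "fr": fr350, "rons": 0.0, "rono": 0.0}, index=ids
    )


def test_graph_radius_basics():
    patient = make_patient([[0, 0, 0], [20, 0, 0]])
    r = rates_frame(["c0", "c1"], [1.0, 1.0])
    assert graph_radius(patient, ["c0", "c1"], "distance_only", r) == pytest.approx(20.0)
    assert graph_radius(patient, ["c0"], "distance_only", r) == 0.0
    assert graph_radius(patient, [], "distance_only", r) is None
    # rate-distance weight: mean rate times distance
    r2 = rates_frame(["c0", "c1"], [2.0, 4.0])
    assert graph_radius(patient, ["c0", "c1"], "rate_distance", r2) == pytest.approx(
        3.0 * 20.0)


def test_graph_radius_matches_floyd_warshall_oracle():
    rng = np.random.default_rng(9)
    for _ in range(50):
        n = int(rng.integers(2, 6))
        coords = rng.uniform(-40, 40, (n, 3))
        patient = make_patient(coords)
        fr = rng.uniform(0.0, 5.0, n)
        r = rates_frame([f"c{i}" for i in range(n)], fr)
        for rule in ("distance_only", "rate_distance"):
            d = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
            w = d if rule == "distance_only" else 0.5 * (fr[:, None] + fr[None, :]) * d
            expected = oracles.graph_radius_complete(
                [[float(v) for v in row] for row in w])
            got = graph_radius(patient, [f"c{i}" for i in range(n)], rule, r)
            assert got == pytest.approx(expected, abs=1e-10)


def test_spatial_frnet_anchors():
    rng = np.random.default_rng(13)
    coords = rng.uniform(-40, 40, (6, 3))
    events = [(i, float(10 * i + 1), "fRonO", 400.0) for i in range(6)]
    patient = make_patient(coords, events=events)
    all_ids = {f"c{i}" for i in range(6)}
    # resecting every FR-generating node zeroes the factor
    assert spatial_frnet(patient, all_ids) == pytest.approx(0.0)
    # a single resected FR node leaves the resected-only radius at 0
    rates = fr_network.event_metrics.contact_rates(patient)
    fr_nodes = [f"c{i}" for i in range(6)]
    r_whole = graph_radius(patient, fr_nodes, "rate_distance", rates)
    assert spatial_frnet(patient, {"c0"}) == pytest.approx(math.sqrt(r_whole))
    assert spatial_frnet(patient, set()) == pytest.approx(math.sqrt(r_whole))
    # no FR-generating nodes: undefined
    empty = make_patient([[0, 0, 0]])
    assert spatial_frnet(empty, set()) is None


def test_temporal_frnet_a():
    a = np.zeros((3, 3))
    a[0, 1] = a[1, 0] = 1.0
    a[1, 2] = a[2, 1] = 0.25  # the long edge (length 4)
    g = MIGraph(["a", "b", "c"], a)
    assert temporal_frnet_a(g, ["a", "b", "c"]) == pytest.approx(1.0)
    # the pair holding the single largest length exceeds the network mean
    assert temporal_frnet_a(g, ["b", "c"]) > 1.0
    assert temporal_frnet_a(g, ["a"]) is None
    rng = np.random.default_rng(21)
    for _ in range(25):
        g = random_mi_graph(rng)
        sub = [g.node_ids[i] for i in
               rng.choice(g.n_nodes, size=rng.integers(2, g.n_nodes + 1),
                          replace=False)]
        got = temporal_frnet_a(g, sub)
        L = lengths_list(g)
        num, _ = oracles.char_path_length(L, [g.node_ids.index(c) for c in sub])
        den, _ = oracles.char_path_length(L, list(range(g.n_nodes)))
        if got is not None and den:
            assert got == pytest.approx(num / den, abs=1e-10)


def test_temporal_frnet_b():
    n = 5
    a = np.full((n, n), 0.3)
    np.fill_diagonal(a, 0.0)
    g = MIGraph([f"c{i}" for i in range(n)], a)
    # everything resected: degenerate convention 1.0
    val, degenerate = temporal_frnet_b(g, set(g.node_ids))
    assert val == 1.0 and degenerate
    # nothing resected on a complete equal-weight graph: mean LE = 1
    val, degenerate = temporal_frnet_b(g, set())
    assert val == pytest.approx(1.0) and not degenerate
    # unresected nodes all isolated
    a2 = np.zeros((3, 3))
    a2[0, 1] = a2[1, 0] = 1.0
    g2 = MIGraph(["a", "b", "c"], a2)
    val, degenerate = temporal_frnet_b(g2, {"a", "b"})
    assert val == 1.0 and degenerate
    # oracle composition on random graphs, unresected scope
    rng = np.random.default_rng(33)
    for _ in range(25):
        g = random_mi_graph(rng)
        res = {g.node_ids[i] for i in
               rng.choice(g.n_nodes, size=rng.integers(0, g.n_nodes),
                          replace=False)}
        val, degenerate = temporal_frnet_b(g, res)
        adj = [[float(v) for v in row] for row in g.adjacency]
        le = [oracles.local_efficiency(adj, i)
              for i, c in enumerate(g.node_ids) if c not in res]
        pos = [v for v in le if v > 0]
        if pos:
            assert not degenerate
            assert val == pytest.approx(sum(pos) / len(pos), abs=1e-10)
        else:
            assert degenerate and val == 1.0


# ---------------------------------------------------------------------------
# graph construction and the feature vector
# ---------------------------------------------------------------------------

def test_build_mi_graph_flags():
    # fewer than 2 FR-generating contacts: degenerate
    p1 = make_patient([[0, 0, 0], [5, 0, 0]],
                      events=[(0, 1.0, "fRonO", 400.0)])
    g1 = build_mi_graph(p1)
    assert "degenerate" in g1.flags and g1.n_nodes == 1
    # no contact with fRonS above 1/min: poor spatial sampling
    assert "poor_spatial_sampling" in g1.flags
    # independent trains: all MI zero, disconnected
    rng = np.random.default_rng(3)
    events = []
    for i in range(3):
        for t in np.sort(rng.uniform(0, 1800, 60)):
            events.append((i, float(t), "fRonO", 400.0))
    p2 = make_patient([[0, 0, 0], [5, 0, 0], [10, 0, 0]], events=events)
    g2 = build_mi_graph(p2)
    assert g2.n_nodes == 3
    assert "disconnected" in g2.flags
    assert np.all(np.isinf(g2.lengths[~np.eye(3, dtype=bool)]))


def test_frons_rate_clears_poor_sampling_flag():
    events = [(0, float(t), "fRonS", 300.0) for t in range(0, 700, 10)] \
        + [(1, 5.0, "fRonO", 400.0)]
    p = make_patient([[0, 0, 0], [5, 0, 0]], events=events, duration_min=30.0)
    assert "poor_spatial_sampling" not in build_mi_graph(p).flags


def test_feature_vector_full_and_empty_resection():
    rng = np.random.default_rng(8)
    # two coupled contacts so the MI network has a finite path
    a = np.sort(rng.uniform(0, 1800, 80))
    keep = rng.random(80) < 0.8
    b = np.sort(a[keep] + rng.normal(0, 0.02, int(keep.sum())))
    events = [(0, float(t), "fRonO", 400.0) for t in a] + \
             [(1, float(t), "fRonO", 400.0) for t in b if 0 <= t <= 1800] + \
             [(2, 7.0, "RonS", 120.0)]
    patient = make_patient([[0, 0, 0], [6, 0, 0], [30, 0, 0]], events=events)
    full = feature_vector(patient, {"c0", "c1", "c2"})
    assert full.fr_rr == pytest.approx(1.0)
    assert full.spatial_frnet == pytest.approx(0.0)
    assert full.temporal_frnet_a == pytest.approx(1.0)
    assert full.temporal_frnet_b == pytest.approx(1.0)
    assert "temporal_frnet_b_degenerate" in full.flags
    empty = feature_vector(patient, set())
    assert empty.fr_rr == 0.0
    assert empty.temporal_frnet_a is None
    assert "temporal_frnet_a_undefined" in empty.flags
    arr = empty.as_array()
    assert np.isnan(arr[2]) and arr[0] == 0.0


def test_halo_coupling_exceeds_core_in_generator(reference_cohort):
    """Planted halo pairs (shared latent trains) carry more MI on
    average than core-involving pairs (independent trains)."""
    halo_vals, core_vals = [], []
    for (patient, gt), g in zip(reference_cohort["cohort"],
                                reference_cohort["graphs"]):
        idx = {c: i for i, c in enumerate(g.node_ids)}
        halo = [idx[c] for c in gt.halo_ids if c in idx]
        core = [idx[c] for c in gt.core_ids if c in idx]
        for i, a in enumerate(halo):
            for b in halo[i + 1:]:
                halo_vals.append(g.adjacency[a, b])
        for a in core:
            for b in halo:
                core_vals.append(g.adjacency[a, b])
    assert np.mean(halo_vals) > np.mean(core_vals)
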