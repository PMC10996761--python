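import numpy as np
import pandas as pd
import pytest

from frnetsim.fr_network import MIGraph
from frnetsim.virtual_resection import (
    ContingencyCounts, VirtualResectionConfig, candidate_order,
    overlap_contingency, run_virtual_resection, sphere_members,
)

from conftest import make_patient


class StubModel:
    """Deterministic stand-in for the outcome SVM."""

    def __init__(self, positive_after=np.inf):
        self.calls = 0
        self.positive_after = positive_after

    def predict_feature_vector(self, fv):
        self.calls += 1
        return self.calls > self.positive_after


def rates_frame(ids, fr350, rons=0.0):
    return pd.DataFrame(
        {"fr350": fr350, "fr": fr350, "rons": rons, "rono": 0.0}, index=ids
    )


def triangle_plus_leaf_graph():
    """d has a single neighbor (LE 0); a, b, c form a triangle (LE > 0)."""
    ids = ["a", "b", "c", "d"]
    adj = np.zeros((4, 4))
    for i, j in [(0, 1), (0, 2), (1, 2)]:
        adj[i, j] = adj[j, i] = 1.0
    adj[0, 3] = adj[3, 0] = 1.0
    return MIGraph(ids, adj)


def test_candidate_order_by_local_efficiency():
    g = triangle_plus_leaf_graph()
    patient = make_patient([[10 * i, 0, 0] for i in range(4)])
    patient.contacts = [c for c in patient.contacts]
    # map graph ids onto contact ids
    g = MIGraph(["c0", "c1", "c2", "c3"], g.adjacency)
    r = rates_frame(["c0", "c1", "c2", "c3"], [3.0, 2.0, 2.0, 1.5])
    order = candidate_order(patient, g, r)
    # the leaf (LE 0) first; the triangle nodes follow, ties broken by
    # higher rate then contact id
    assert order[0] == "c3"
    assert order[1] == "c0"  # highest rate among the equal-LE triangle
    assert order[2:] == ["c1", "c2"]  # rate tie -> lexicographic


def test_candidate_order_fallback_by_rate():
    g = MIGraph(["c0", "c1", "c2"], np.zeros((3, 3)))
    patient = make_patient([[0, 0, 0], [5, 0, 0], [10, 0, 0]])
    r = rates_frame(["c0", "c1", "c2"], [0.2, 0.9, 0.5])
    assert candidate_order(patient, g, r) == ["c1", "c2", "c0"]


def test_candidate_order_requires_fr_nodes():
    g = MIGraph([], np.zeros((0, 0)))
    patient = make_patient([[0, 0, 0]])
    with pytest.raises(ValueError, match="poor sampling"):
        candidate_order(patient, g, rates_frame([], []))


def test_sphere_members_closed_ball_and_hemisphere():
    patient = make_patient(
        [[10, 0, 0], [20, 0, 0], [-2, 0, 0], [10, 10, 0]],
    )  # c2 is contralateral (x < 0)
    members = sphere_members(patient.contacts, np.array([10.0, 0, 0]), 10.0, "R")
    assert members == {"c0", "c1", "c3"}  # c1 exactly at the radius: included
    # contralateral contact 2 mm away is excluded
    members = sphere_members(patient.contacts, np.array([0.0, 0, 0]), 10.0, "R")
    assert "c2" not in members


def test_radius_arithmetic_on_hand_built_patient():
    """Radius sequence reproduces max(prev, dist + 10) exactly.

    Independent Poisson trains give zero MI everywhere, so every node
    has LE 0 and the candidate order falls to the rate tie-break:
    c0 > c1 > c2 > c3.
    """
    rng = np.random.default_rng(0)
    coords = [[20, 0, 0], [20, 5, 0], [20, 30, 0], [20, 60, 0]]
    events = []
    for i, n_ev in enumerate([90, 80, 70, 60]):  # rates 3,...,2 per min
        events += [(i, float(t), "fRonO", 400.0)
                   for t in np.sort(rng.uniform(0, 1800, n_ev))]
    patient = make_patient(coords, events=events, lobes=["temporal"] * 4)
    model = StubModel()  # never positive
    trace = run_virtual_resection(patient, model)
    radii = [s.radius_mm for s in trace.steps]
    # center c0; c1 within 10 mm of it so iteration 1 resects both;
    # c2 at 30 mm -> radius 40; c3 at 60 mm -> radius 70
    assert trace.center_contact == "c0"
    assert radii[0] == 10.0
    assert radii[1] == pytest.approx(40.0)
    assert radii[2] == pytest.approx(70.0)
    assert trace.termination == "candidates_exhausted"
    sets = [s.resected for s in trace.steps]
    assert sets[0] == {"c0", "c1"}
    assert sets[1] == {"c0", "c1", "c2"}
    assert sets[2] == {"c0", "c1", "c2", "c3"}


def test_three_lobe_stop():
    coords = [[20, 30, 0], [20, -20, 20], [20, -70, 0]]
    lobes = ["frontal", "parietal", "occipital"]
    events = []
    for i in range(3):
        events += [(i, 0.1 + j * 10.0, "fRonO", 400.0) for j in range(90)]
    patient = make_patient(coords, events=events, lobes=lobes)
    trace = run_virtual_resection(patient, StubModel())
    assert trace.termination == "three_lobe_stop"
    assert trace.steps[-1].n_lobes >= 3
    # it fired exactly when the set first spanned 3 lobes
    for s in trace.steps[:-1]:
        assert s.n_lobes < 3


def test_stops_at_first_positive_label():
    coords = [[20, 0, 0], [20, 30, 0], [20, 60, 0]]
    events = []
    for i in range(3):
        events += [(i, 0.1 + j * 10.0, "fRonO", 400.0) for j in range(90)]
    patient = make_patient(coords, events=events)
    trace = run_virtual_resection(patient, StubModel(positive_after=1))
    assert trace.termination == "seizure_free"
    assert len(trace.steps) == 2
    assert trace.steps[-1].svm_seizure_free


def test_nestedness_and_monotone_fr_rr(reference_cohort):
    """Resected sets are nested, radii never shrink, and the FR
    resection ratio never decreases across iterations."""
    patient = reference_cohort["patients"][0]
    g = reference_cohort["graphs"][0]
    r = reference_cohort["rates"][0]
    trace = run_virtual_resection(patient, StubModel(), graph=g, rates=r)
    prev = None
    for s in trace.steps:
        if prev is not None:
            assert s.resected >= prev.resected
            assert s.radius_mm >= prev.radius_mm
            assert s.features.fr_rr >= prev.features.fr_rr - 1e-12
        prev = s


def test_trace_determinism(reference_cohort):
    patient = reference_cohort["patients"][1]
    g = reference_cohort["graphs"][1]
    r = reference_cohort["rates"][1]
    model = reference_cohort["model"]
    t1 = run_virtual_resection(patient, model, graph=g, rates=r)
    t2 = run_virtual_resection(patient, model, graph=g, rates=r)
    assert t1.termination == t2.termination
    assert [s.resected for s in t1.steps] == [s.resected for s in t2.steps]
    pd.testing.assert_frame_equal(t1.to_frame(), t2.to_frame())


def test_overlap_contingency():
    universe = {f"c{i}" for i in range(20)}
    actual = {f"c{i}" for i in range(8)}
    # identical sets: everything perfect
    c = overlap_contingency(actual, actual, universe)
    for v in (c.sensitivity, c.specificity, c.ppv, c.npv, c.accuracy, c.f1):
        assert v == 1.0
    assert c.novel_r == 0.0
    assert c.tp + c.fp + c.tn + c.fn == 20
    # superset with extras
    virtual = actual | {"c10", "c11"}
    c2 = overlap_contingency(virtual, actual, universe)
    assert c2.percent_r == 1.0
    assert c2.novel_r == pytest.approx(0.2)
    # percent_r is sensitivity by definition
    rng = np.random.default_rng(0)
    for _ in range(20):
        v = {f"c{i}" for i in rng.choice(20, rng.integers(0, 20), replace=False)}
        a = {f"c{i}" for i in rng.choice(20, rng.integers(1, 20), replace=False)}
        cc = overlap_contingency(v, a, universe)
        assert cc.percent_r == cc.sensitivity
    # empty actual set: sensitivity undefined
    c3 = overlap_contingency({"c0"}, set(), universe)
    assert c3.sensitivity is None and c3.percent_r is None


def test_f1_formula():
    c = ContingencyCounts(tp=2, fp=2, tn=0, fn=0)  # ppv 0.5, sens 1.0
    assert c.f1 == pytest.approx(2.0 / 3.0)
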