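"""Iterative spherical virtual resection targeting autonomous FR sites.

The simulator grows a resection sphere over the patient's SEEG contact
cloud.  Candidates are the MI-network nodes with an FR>350 rate above
1/min, visited in order of increasing local efficiency (most temporally
autonomous first); when those run out the remaining FR-generating nodes
follow in order of decreasing rate.  The sphere starts at 10 mm around
the first candidate and, for each later candidate outside it, expands to
the candidate's distance from the (fixed) center plus a 10 mm surgical
buffer — never shrinking.  Contacts contralateral to the center never
enter the resected set.  After every change of the resected set the four
FR factors are recomputed and a trained outcome SVM is queried; the run
stops at the first seizure-free label, when the resected set spans three
brain lobes (designated not seizure free), or when candidates are
exhausted.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import event_metrics, fr_network
from .data_model import Contact, PatientRecord
from .fr_network import FRFeatureVector, MIGraph
from .outcome_svm import FROutcomeClassifier

__all__ = [
    "VirtualResectionConfig", "VirtualResectionStep", "VirtualResectionTrace",
    "ContingencyCounts", "candidate_order", "sphere_members",
    "run_virtual_resection", "overlap_contingency",
]


@dataclasses.dataclass(frozen=True)
class VirtualResectionConfig:
    initial_radius_mm: float = 10.0
    buffer_mm: float = 10.0
    candidate_rate_per_min: float = 1.0
    max_lobes: int = 3
    frnet_b_scope: str = "unresected"


@dataclasses.dataclass(frozen=True)
class VirtualResectionStep:
    index: int
    radius_mm: float
    resected: frozenset[str]
    features: FRFeatureVector
    soz_rr: Optional[float]
    rons_rr: Optional[float]
    svm_seizure_free: bool
    n_lobes: int


@dataclasses.dataclass
class VirtualResectionTrace:
    patient_id: str
    center_contact: str
    center: np.ndarray
    steps: list[VirtualResectionStep]
    termination: str  # seizure_free | three_lobe_stop | candidates_exhausted

    @property
    def final_resected(self) -> frozenset[str]:
        return self.steps[-1].resected

    @property
    def final_radius_mm(self) -> float:
        return self.steps[-1].radius_mm

    @property
    def seizure_free(self) -> bool:
        return self.termination == "seizure_free"

    def to_frame(self) -> pd.DataFrame:
        """One row per iteration, mirroring the per-iteration metric panels."""
        rows = []
        for s in self.steps:
            fv = s.features
            rows.append({
                "iteration": s.index,
                "radius_mm": s.radius_mm,
                "n_resected": len(s.resected),
                "soz_rr": s.soz_rr,
                "rons_rr": s.rons_rr,
                "fr_rr": fv.fr_rr,
                "spatial_frnet": fv.spatial_frnet,
                "temporal_frnet_a": fv.temporal_frnet_a,
                "temporal_frnet_b": fv.temporal_frnet_b,
                "svm_label": s.svm_seizure_free,
                "n_lobes": s.n_lobes,
            })
        return pd.DataFrame(rows)


def candidate_order(
    patient: PatientRecord,
    graph: MIGraph,
    rates: pd.DataFrame,
    rate_threshold: float = 1.0,
) -> list[str]:
    """Candidate targets, most autonomous high-rate nodes first.

    Primary: MI-network nodes with FR>350 rate > ``rate_threshold``/min,
    ascending local efficiency (ties: higher rate, then contact id).
    Fallback (appended): remaining FR-generating nodes, descending rate
    (ties: contact id).
    """
    if graph.n_nodes == 0:
        raise ValueError("no FR-generating contacts (poor sampling)")
    le = fr_network.nodal_local_efficiency(graph)
    rate = rates["fr350"]
    primary = [c for c in graph.node_ids if rate[c] > rate_threshold]
    primary.sort(key=lambda c: (le[c], -rate[c], c))
    fallback = [c for c in graph.node_ids if rate[c] <= rate_threshold]
    fallback.sort(key=lambda c: (-rate[c], c))
    return primary + fallback


def sphere_members(
    contacts: Sequence[Contact],
    center: np.ndarray,
    radius_mm: float,
    center_hemisphere: str,
) -> frozenset[str]:
    """Contacts within the closed ball, excluding the contralateral hemisphere."""
    center = np.asarray(center, dtype=float)
    out = []
    for c in contacts:
        if c.hemisphere != center_hemisphere:
            continue
        if float(np.linalg.norm(c.coord - center)) <= radius_mm:
            out.append(c.contact_id)
    return frozenset(out)


def _count_lobes(patient: PatientRecord, resected: Iterable[str]) -> int:
    return len({patient.contact(c).lobe for c in resected})


def run_virtual_resection(
    patient: PatientRecord,
    model: FROutcomeClassifier,
    config: VirtualResectionConfig | None = None,
    graph: MIGraph | None = None,
    rates: pd.DataFrame | None = None,
) -> VirtualResectionTrace:
    """Run the iterative simulator; deterministic for fixed inputs."""
    config = config or VirtualResectionConfig()
    if rates is None:
        rates = event_metrics.contact_rates(patient)
    if graph is None:
        graph = fr_network.build_mi_graph(patient, rates=rates)
    order = candidate_order(patient, graph, rates, config.candidate_rate_per_min)

    center_contact = order[0]
    center = patient.contact(center_contact).coord
    hemi = patient.contact(center_contact).hemisphere
    radius = config.initial_radius_mm

    steps: list[VirtualResectionStep] = []
    resected: frozenset[str] = frozenset()
    termination = "candidates_exhausted"

    def evaluate(radius_mm: float, new_set: frozenset[str]) -> VirtualResectionStep:
        fv = fr_network.feature_vector(
            patient, new_set, graph=graph, rates=rates,
            frnet_b_scope=config.frnet_b_scope,
        )
        label = model.predict_feature_vector(fv)
        return VirtualResectionStep(
            index=len(steps) + 1,
            radius_mm=radius_mm,
            resected=new_set,
            features=fv,
            soz_rr=event_metrics.soz_resection_ratio(patient, new_set),
            rons_rr=event_metrics.event_resection_ratio(patient, "rons", new_set),
            svm_seizure_free=label,
            n_lobes=_count_lobes(patient, new_set),
        )

    for k, cand in enumerate(order):
        if cand in resected:
            # already covered by the current sphere: no new evaluation
            continue
        if k > 0:
            dist = float(np.linalg.norm(patient.contact(cand).coord - center))
            radius = max(radius, dist + config.buffer_mm)
        new_set = sphere_members(patient.contacts, center, radius, hemi)
        if new_set == resected:
            # contralateral candidate: consumed without changing the set
            continue
        step = evaluate(radius, new_set)
        steps.append(step)
        resected = new_set
        if step.svm_seizure_free:
            termination = "seizure_free"
            break
        if step.n_lobes >= config.max_lobes:
            termination = "three_lobe_stop"
            break

    if not steps:  # center evaluation always happens, even if set never grows
        steps.append(evaluate(radius, sphere_members(
            patient.contacts, center, radius, hemi)))
    return VirtualResectionTrace(
        patient_id=patient.patient_id,
        center_contact=center_contact,
        center=center,
        steps=steps,
        termination=termination,
    )


@dataclasses.dataclass(frozen=True)
class ContingencyCounts:
    """Contact-level confusion counts of a virtual vs. actual resection."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> Optional[float]:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def specificity(self) -> Optional[float]:
        d = self.tn + self.fp
        return self.tn / d if d else None

    @property
    def ppv(self) -> Optional[float]:
        d = self.tp + self.fp
        return self.tp / d if d else None

    @property
    def npv(self) -> Optional[float]:
        d = self.tn + self.fn
        return self.tn / d if d else None

    @property
    def accuracy(self) -> Optional[float]:
        return (self.tp + self.tn) / self.n if self.n else None

    @property
    def f1(self) -> Optional[float]:
        p, s = self.ppv, self.sensitivity
        if p is None or s is None or (p + s) == 0:
            return None
        return 2.0 * p * s / (p + s)

    @property
    def percent_r(self) -> Optional[float]:
        """Fraction of the actual resection covered by the virtual set."""
        return self.sensitivity

    @property
    def novel_r(self) -> Optional[float]:
        """Fraction of the virtual set outside the actual resection."""
        d = self.tp + self.fp
        return self.fp / d if d else None

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "ppv": self.ppv, "npv": self.npv, "accuracy": self.accuracy,
            "f1": self.f1, "percent_r": self.percent_r, "novel_r": self.novel_r,
        }


def overlap_contingency(
    virtual: Iterable[str], actual: Iterable[str], universe: Iterable[str]
) -> ContingencyCounts:
    """Confusion counts over the contact universe (TP = in both sets)."""
    virtual, actual, universe = set(virtual), set(actual), set(universe)
    if not virtual <= universe or not actual <= universe:
        raise ValueError("virtual/actual sets must be subsets of the universe")
    tp = len(virtual & actual)
    fp = len(virtual - actual)
    fn = len(actual - virtual)
    tn = len(universe) - tp - fp - fn
    return ContingencyCounts(tp=tp, fp=fp, tn=tn, fn=fn)
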