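"""Responsive neurostimulation (RNS) geometry and stimulation metrics.

An RNS implant carries two leads of four contacts each.  The cortical
territory a lead effectively stimulates is approximated as every
pre-implant SEEG contact strictly within 15 mm of any of the eight RNS
contacts (a monopolar-field range for 1-3 mA stimulation).  Over that
stimulated set three metrics are computed:

* SOZ stimulation ratio — fraction of seizure-onset-zone contacts
  stimulated (contact counts);
* FR stimulation ratio — fraction of FR>350 events on stimulated
  contacts (event counts);
* RNS temporal FRnet — global efficiency of the MI subnetwork induced
  on the stimulated contacts plus their first-degree MI neighbors
  (low values indicate stimulation of temporally autonomous FR sites).

Virtual lead placement re-targets each four-contact lead to run along
the SEEG shaft holding the highest-rate FR>350 contact (per hemisphere
for bilateral implants).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import event_metrics, fr_network
from .data_model import Contact, PatientRecord, RNSLeads
from .fr_network import MIGraph

__all__ = ["RNSMetrics", "stimulated_set", "rns_metrics", "virtual_placement"]

DEFAULT_FIELD_RADIUS_MM = 15.0


@dataclasses.dataclass(frozen=True)
class RNSMetrics:
    soz_sr: Optional[float]
    fr_sr: Optional[float]
    rns_temporal_frnet: Optional[float]
    stimulated: frozenset[str]
    neighbors: frozenset[str]
    flags: tuple[str, ...] = ()


def stimulated_set(
    contacts: Sequence[Contact],
    leads: RNSLeads,
    field_radius_mm: float = DEFAULT_FIELD_RADIUS_MM,
) -> frozenset[str]:
    """SEEG contacts strictly within the stimulation field of any RNS contact."""
    coords = np.array([c.coord for c in contacts])
    if coords.size == 0:
        return frozenset()
    d = np.linalg.norm(
        coords[:, None, :] - leads.stim_coords[None, :, :], axis=2
    ).min(axis=1)
    return frozenset(c.contact_id for c, di in zip(contacts, d)
                     if di < field_radius_mm)


def rns_metrics(
    patient: PatientRecord,
    stim: Iterable[str],
    graph: MIGraph | None = None,
) -> RNSMetrics:
    """Stimulation ratios and stimulated global efficiency for a contact set."""
    stim = set(stim)
    if graph is None:
        graph = fr_network.build_mi_graph(patient)
    flags: list[str] = []
    soz_sr = event_metrics.soz_stimulation_ratio(patient, stim)
    if soz_sr is None:
        flags.append("soz_sr_undefined")
    fr_sr = event_metrics.event_stimulation_ratio(patient, "fr350", stim)
    if fr_sr is None:
        flags.append("fr_sr_undefined")

    stim_nodes = [c for c in graph.node_ids if c in stim]
    idx = graph.index_of(stim_nodes)
    nbr_mask = np.zeros(graph.n_nodes, dtype=bool)
    if idx.size:
        nbr_mask = (graph.adjacency[idx] > 0).any(axis=0)
    neighbors = frozenset(
        c for c, m in zip(graph.node_ids, nbr_mask) if m and c not in stim
    )
    sub_nodes = list(stim_nodes) + sorted(neighbors)
    sge = fr_network.global_efficiency(graph, sub_nodes) if len(sub_nodes) >= 2 else None
    if sge is None:
        flags.append("rns_temporal_frnet_undefined")
    return RNSMetrics(
        soz_sr=soz_sr, fr_sr=fr_sr, rns_temporal_frnet=sge,
        stimulated=frozenset(stim), neighbors=neighbors, flags=tuple(flags),
    )


def _shaft_order(contacts: Sequence[Contact]) -> list[Contact]:
    """Order a shaft's contacts along its principal axis."""
    coords = np.array([c.coord for c in contacts])
    center = coords.mean(axis=0)
    if len(contacts) == 1:
        return list(contacts)
    # principal direction via the leading right singular vector
    _, _, vt = np.linalg.svd(coords - center, full_matrices=False)
    proj = (coords - center) @ vt[0]
    return [contacts[i] for i in np.argsort(proj, kind="stable")]


def _lead_around(
    patient: PatientRecord, anchor: Contact, n_contacts: int = 4
) -> list[Contact]:
    """Four contiguous contacts on the anchor's shaft, centered on it.

    A window of positions (i-1 .. i+2) around the anchor, clipped at the
    shaft's ends.  Shafts with fewer than four contacts contribute all
    their contacts, padded with the spatially nearest contacts from
    other shafts.
    """
    shaft = [c for c in patient.contacts if c.shaft_id == anchor.shaft_id]
    ordered = _shaft_order(shaft)
    i = next(k for k, c in enumerate(ordered) if c.contact_id == anchor.contact_id)
    if len(ordered) >= n_contacts:
        start = min(max(i - 1, 0), len(ordered) - n_contacts)
        return ordered[start:start + n_contacts]
    lead = list(ordered)
    others = [c for c in patient.contacts if c.shaft_id != anchor.shaft_id]
    others.sort(key=lambda c: (float(np.linalg.norm(c.coord - anchor.coord)),
                               c.contact_id))
    lead.extend(others[: n_contacts - len(lead)])
    if len(lead) < n_contacts:
        raise ValueError("not enough contacts to assemble a 4-contact lead")
    return lead


def virtual_placement(
    patient: PatientRecord,
    rates: pd.DataFrame | None = None,
    bilateral: bool | None = None,
) -> RNSLeads:
    """Re-target the two RNS leads to the highest-rate FR>350 sites.

    Lead 1 follows the shaft holding the globally highest-rate contact.
    Lead 2: for a bilateral implant, the same construction around the
    highest-rate contact of the opposite hemisphere; otherwise around
    the highest-rate contact on a different shaft.  ``bilateral``
    defaults to the patient's actual implant laterality (unilateral when
    the patient has none recorded).
    """
    if rates is None:
        rates = event_metrics.contact_rates(patient)
    if bilateral is None:
        bilateral = patient.rns.bilateral if patient.rns is not None else False
    fr = rates["fr350"]
    ranked = sorted(patient.contacts,
                    key=lambda c: (-fr[c.contact_id], c.contact_id))
    top = ranked[0]
    lead1 = _lead_around(patient, top)
    if bilateral:
        pool = [c for c in ranked if c.hemisphere != top.hemisphere]
        if not pool:
            raise ValueError("bilateral placement requested but all contacts "
                             "are in one hemisphere")
    else:
        pool = [c for c in ranked if c.shaft_id != top.shaft_id]
        if not pool:
            raise ValueError("no second shaft available for lead 2")
    lead2 = _lead_around(patient, pool[0])
    coords = np.array([c.coord for c in lead1 + lead2])
    lead_types = (patient.rns.lead_types if patient.rns is not None
                  else ("depth", "depth"))
    return RNSLeads(stim_coords=coords, lead_types=tuple(lead_types))


def rns_report_row(
    patient: PatientRecord,
    graph: MIGraph | None = None,
    rates: pd.DataFrame | None = None,
    field_radius_mm: float = DEFAULT_FIELD_RADIUS_MM,
) -> dict:
    """Actual vs. virtual stimulation metrics for one RNS patient."""
    if patient.rns is None:
        raise ValueError(f"patient {patient.patient_id} has no RNS leads")
    if rates is None:
        rates = event_metrics.contact_rates(patient)
    if graph is None:
        graph = fr_network.build_mi_graph(patient, rates=rates)
    actual = rns_metrics(
        patient, stimulated_set(patient.contacts, patient.rns, field_radius_mm),
        graph,
    )
    vleads = virtual_placement(patient, rates)
    virtual = rns_metrics(
        patient, stimulated_set(patient.contacts, vleads, field_radius_mm),
        graph,
    )
    return {
        "patient_id": patient.patient_id,
        "actual_soz_sr": actual.soz_sr,
        "actual_fr_sr": actual.fr_sr,
        "actual_rns_temporal_frnet": actual.rns_temporal_frnet,
        "virtual_soz_sr": virtual.soz_sr,
        "virtual_fr_sr": virtual.fr_sr,
        "virtual_rns_temporal_frnet": virtual.rns_temporal_frnet,
    }
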