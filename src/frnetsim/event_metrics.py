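"""Event-family filters, per-contact rates, and resection/stimulation ratios.

The event family that drives every network metric downstream is the
high-band fast ripple family, "FR>350": fast ripples on oscillations with
peak frequency above 350 Hz, together with *all* fast ripples on spikes
(200-600 Hz).  The broader families (all FR, ripples on spikes, ripples
on oscillations) are used for descriptive resection ratios only.
"""

from __future__ import annotations

from typing import Iterable, Optional

import pandas as pd

from .data_model import EventRecord, PatientRecord

#: Event families, keyed by the name used in rate tables and reports.
FAMILIES = ("fr350", "fr", "rons", "rono")


def is_fr350(event: EventRecord) -> bool:
    """True iff the event belongs to the FR>350 family.

    Membership: fRonO with peak frequency strictly above 350 Hz, or any
    fRonS (whole 200-600 Hz band).
    """
    if event.category == "fRonS":
        return True
    return event.category == "fRonO" and event.peak_freq_hz > 350.0


def in_family(event: EventRecord, family: str) -> bool:
    """Membership test for one of :data:`FAMILIES`."""
    if family == "fr350":
        return is_fr350(event)
    if family == "fr":
        return event.category in ("fRonO", "fRonS")
    if family == "rons":
        return event.category == "RonS"
    if family == "rono":
        return event.category == "RonO"
    raise ValueError(f"unknown event family {family!r}")


def contact_rates(patient: PatientRecord) -> pd.DataFrame:
    """Per-contact event rates (events/min) for every family.

    Returns a DataFrame indexed by ``contact_id`` (all contacts, in
    patient order) with one column per family; contacts without events
    have rate 0.
    """
    if patient.duration_min <= 0:
        raise ValueError("duration_min must be > 0")
    counts = {f: dict.fromkeys(patient.contact_ids, 0) for f in FAMILIES}
    for e in patient.events:
        for f in FAMILIES:
            if in_family(e, f):
                counts[f][e.contact_id] += 1
    df = pd.DataFrame(counts, index=patient.contact_ids, dtype=float)
    df.index.name = "contact_id"
    return df / patient.duration_min


def event_resection_ratio(
    patient: PatientRecord, family: str, resected: Iterable[str]
) -> Optional[float]:
    """Fraction of the family's events recorded on resected contacts.

    Numerator: events of the family on contacts in ``resected``;
    denominator: all events of the family on any contact.  Returns
    ``None`` when the patient has no events of the family (an undefined
    0/0, never silently zero).
    """
    resected = set(resected)
    total = 0
    hit = 0
    for e in patient.events:
        if in_family(e, family):
            total += 1
            if e.contact_id in resected:
                hit += 1
    if total == 0:
        return None
    return hit / total


def soz_resection_ratio(
    patient: PatientRecord, resected: Iterable[str]
) -> Optional[float]:
    """Fraction of seizure-onset-zone contacts inside the resected set.

    Contact-count based (unlike the event-count resection ratios).
    Returns ``None`` when the patient has no SOZ contacts.
    """
    soz = patient.soz_set
    if not soz:
        return None
    return len(soz & set(resected)) / len(soz)


# The RNS stimulation ratios are the same quantities evaluated against the
# stimulated contact set instead of the resected set.
def event_stimulation_ratio(
    patient: PatientRecord, family: str, stimulated: Iterable[str]
) -> Optional[float]:
    """Event-count stimulation ratio (alias of the resection-ratio formula)."""
    return event_resection_ratio(patient, family, stimulated)


def soz_stimulation_ratio(
    patient: PatientRecord, stimulated: Iterable[str]
) -> Optional[float]:
    """SOZ contact-count stimulation ratio."""
    return soz_resection_ratio(patient, stimulated)
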