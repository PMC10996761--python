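from __future__ import annotations

import sys
import warnings
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from frnetsim import event_metrics, fr_network, outcome_svm, synthetic_data
from frnetsim.data_model import Contact, EventRecord, PatientRecord

REFERENCE_SEED = 1


def make_patient(
    coords,
    events=(),
    duration_min=30.0,
    soz=(),
    resected=(),
    hemispheres=None,
    lobes=None,
    shafts=None,
    engel=None,
    rns=None,
    patient_id="TEST",
) -> PatientRecord:
    """Hand-built patient: coords is a list of 3-vectors; events are
    (contact_index, onset_s, category, peak_freq_hz) tuples."""
    coords = [np.asarray(c, dtype=float) for c in coords]
    n = len(coords)
    ids = [f"c{i}" for i in range(n)]
    hemispheres = hemispheres or ["R" if c[0] >= 0 else "L" for c in coords]
    lobes = lobes or ["temporal"] * n
    shafts = shafts or ["sh0"] * n
    contacts = [
        Contact(
            contact_id=ids[i], shaft_id=shafts[i], coord=coords[i],
            hemisphere=hemispheres[i], lobe=lobes[i],
            is_soz=i in set(soz), is_resected=i in set(resected),
        )
        for i in range(n)
    ]
    evs = [EventRecord(ids[i], float(t), cat, float(f)) for i, t, cat, f in events]
    return PatientRecord(
        patient_id=patient_id, contacts=contacts, events=evs,
        duration_min=duration_min, engel=engel, rns=rns,
    )


@pytest.fixture(scope="session")
def reference_cohort():
    """The fixed-seed synthetic reference cohort with everything derived:
    per-patient MI graphs and rate tables, the factor matrix, labels, and
    an outcome SVM trained on the actual resections."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cohort = synthetic_data.generate_cohort(seed=REFERENCE_SEED)
        graphs, rates = [], []
        for p, _ in cohort:
            r = event_metrics.contact_rates(p)
            rates.append(r)
            graphs.append(fr_network.build_mi_graph(p, rates=r))
        patients = [p for p, _ in cohort]
        X, y = outcome_svm.cohort_features(patients, graphs=graphs, rates=rates)
        model = outcome_svm.train(X, y)
    return {
        "cohort": cohort,
        "patients": patients,
        "truths": [gt for _, gt in cohort],
        "graphs": graphs,
        "rates": rates,
        "X": X,
        "y": y,
        "model": model,
    }
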