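"""Domain types and file I/O for SEEG fast-ripple network analysis.

A *patient* here is an SEEG implant: a set of electrode contacts with MNI
coordinates and clinical annotations (seizure-onset-zone membership,
resection membership), plus a catalog of detected high-frequency
oscillation (HFO) events attributed to those contacts.  Raw iEEG never
enters this package; HFO detection is upstream.

File dialects are deliberately plain: a TSV for contacts, a CSV for
events, and a JSON sidecar for patient metadata.  All coordinates are MNI
millimetres and all distances Euclidean in mm.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

HEMISPHERES = ("L", "R")
LOBES = ("frontal", "temporal", "parietal", "occipital", "insula", "other")
#: HFO event categories: fast ripple (fR, 200-600 Hz) or ripple (R, 80-200 Hz),
#: each either on a background oscillation (onO) or superimposed on an
#: epileptiform spike (onS).
CATEGORIES = ("fRonO", "fRonS", "RonO", "RonS")

RIPPLE_BAND = (80.0, 200.0)
FR_BAND = (200.0, 600.0)

CONTACT_COLUMNS = [
    "contact_id", "shaft_id", "x_mm", "y_mm", "z_mm",
    "hemisphere", "lobe", "region", "is_soz", "is_resected",
]
EVENT_COLUMNS = ["contact_id", "onset_s", "category", "peak_freq_hz"]


class SchemaError(ValueError):
    """A required column or key is missing or malformed."""


class ReferentialError(ValueError):
    """An event references a contact that does not exist."""


@dataclasses.dataclass(frozen=True)
class Contact:
    """One SEEG recording site.

    Parameters
    ----------
    contact_id : str
        Unique identifier within a patient (e.g. ``"LA3"``).
    shaft_id : str
        The depth electrode (shaft) the contact belongs to.
    coord : ndarray of shape (3,)
        MNI coordinate in millimetres.
    hemisphere : {"L", "R"}
    lobe : str
        One of :data:`LOBES`.
    region : str
        Free-text atlas label.
    is_soz : bool
        Clinically delineated seizure-onset-zone membership.
    is_resected : bool
        Whether the contact fell inside the actual resection cavity.
    """

    contact_id: str
    shaft_id: str
    coord: np.ndarray
    hemisphere: str
    lobe: str
    region: str = ""
    is_soz: bool = False
    is_resected: bool = False

    def __post_init__(self) -> None:
        coord = np.asarray(self.coord, dtype=float)
        if coord.shape != (3,) or not np.all(np.isfinite(coord)):
            raise ValueError(
                f"contact {self.contact_id!r}: coord must be a finite 3-vector"
            )
        object.__setattr__(self, "coord", coord)
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(
                f"contact {self.contact_id!r}: hemisphere {self.hemisphere!r} "
                f"not in {HEMISPHERES}"
            )
        if self.lobe not in LOBES:
            raise ValueError(
                f"contact {self.contact_id!r}: lobe {self.lobe!r} not in {LOBES}"
            )


@dataclasses.dataclass(frozen=True)
class EventRecord:
    """One detected HFO event.

    ``onset_s`` is the event onset in seconds from the start of the
    analyzed epoch; ``peak_freq_hz`` must fall in the band implied by the
    category (ripples 80-200 Hz, fast ripples 200-600 Hz).
    """

    contact_id: str
    onset_s: float
    category: str
    peak_freq_hz: float

    def __post_init__(self) -> None:
        if self.onset_s < 0:
            raise ValueError(f"event on {self.contact_id!r}: onset_s < 0")
        if self.category not in CATEGORIES:
            raise ValueError(
                f"event on {self.contact_id!r}: category {self.category!r} "
                f"not in {CATEGORIES}"
            )
        lo, hi = FR_BAND if self.category.startswith("f") else RIPPLE_BAND
        if not (lo < self.peak_freq_hz <= hi):
            raise ValueError(
                f"event on {self.contact_id!r}: peak frequency "
                f"{self.peak_freq_hz} Hz outside ({lo}, {hi}] for "
                f"category {self.category}"
            )


@dataclasses.dataclass(frozen=True)
class RNSLeads:
    """Geometry of a two-lead responsive neurostimulation (RNS) implant.

    Each lead carries four contacts, so ``stim_coords`` holds exactly
    eight MNI coordinates (lead 1 first).  ``bilateral`` is true iff the
    two leads' centroids lie in opposite hemispheres (sign of x).
    """

    stim_coords: np.ndarray
    lead_types: tuple[str, str] = ("depth", "depth")

    def __post_init__(self) -> None:
        coords = np.asarray(self.stim_coords, dtype=float)
        if coords.shape != (8, 3):
            raise ValueError("RNS leads require exactly 8 coordinates (2 leads x 4)")
        if not np.all(np.isfinite(coords)):
            raise ValueError("RNS lead coordinates must be finite")
        for t in self.lead_types:
            if t not in ("depth", "strip"):
                raise ValueError(f"unknown lead type {t!r}")
        object.__setattr__(self, "stim_coords", coords)

    @property
    def bilateral(self) -> bool:
        m1 = self.stim_coords[:4, 0].mean()
        m2 = self.stim_coords[4:, 0].mean()
        return bool(m1 * m2 < 0)


def engel_seizure_free(engel: Optional[str]) -> Optional[bool]:
    """Dichotomize an Engel outcome string.

    Engel class I (any letter: IA-ID) maps to seizure free; classes
    II-IV map to not seizure free.  ``None`` stays ``None`` (no outcome).
    """
    if engel is None:
        return None
    s = str(engel).strip().upper().replace("ENGEL", "").strip()
    if not s:
        return None
    # leading roman numeral: IV before III before II before I
    for prefix, cls in (("IV", 4), ("III", 3), ("II", 2), ("I", 1)):
        if s.startswith(prefix):
            return cls == 1
    raise ValueError(f"unrecognized Engel outcome {engel!r}")


@dataclasses.dataclass
class PatientRecord:
    """A validated patient: contacts, events, duration, and outcome."""

    patient_id: str
    contacts: list[Contact]
    events: list[EventRecord]
    duration_min: float
    engel: Optional[str] = None
    rns: Optional[RNSLeads] = None

    def __post_init__(self) -> None:
        if self.duration_min <= 0:
            raise ValueError("duration_min must be > 0")
        ids = [c.contact_id for c in self.contacts]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate contact ids: {dup}")
        known = set(ids)
        orphans = sorted({e.contact_id for e in self.events if e.contact_id not in known})
        if orphans:
            raise ReferentialError(
                f"events reference unknown contacts: {orphans}"
            )
        dur_s = self.duration_min * 60.0
        late = [e for e in self.events if e.onset_s > dur_s]
        if late:
            raise ValueError(
                f"{len(late)} events have onsets beyond the recording duration"
            )
        if not (10.0 <= self.duration_min <= 60.0):
            warnings.warn(
                f"patient {self.patient_id}: duration {self.duration_min} min "
                "outside the usual 10-60 min analysis window",
                stacklevel=2,
            )

    @property
    def seizure_free(self) -> Optional[bool]:
        return engel_seizure_free(self.engel)

    @property
    def contact_ids(self) -> list[str]:
        return [c.contact_id for c in self.contacts]

    def contact(self, contact_id: str) -> Contact:
        for c in self.contacts:
            if c.contact_id == contact_id:
                return c
        raise KeyError(contact_id)

    @property
    def coords(self) -> np.ndarray:
        """(n_contacts, 3) coordinate array in contact order."""
        return np.array([c.coord for c in self.contacts])

    @property
    def resected_set(self) -> set[str]:
        return {c.contact_id for c in self.contacts if c.is_resected}

    @property
    def soz_set(self) -> set[str]:
        return {c.contact_id for c in self.contacts if c.is_soz}

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.contact_id, e.onset_s, e.category, e.peak_freq_hz) for e in self.events],
            columns=EVENT_COLUMNS,
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {missing}")


def _parse_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    if isinstance(v, (int, np.integer, float, np.floating)):
        return bool(int(v))
    s = str(v).strip().lower()
    if s in ("true", "t", "1", "yes"):
        return True
    if s in ("false", "f", "0", "no"):
        return False
    raise SchemaError(f"cannot interpret {v!r} as a boolean")


def read_contacts(path) -> list[Contact]:
    """Read the contacts TSV (columns of :data:`CONTACT_COLUMNS`)."""
    df = pd.read_csv(path, sep="\t", dtype={"contact_id": str, "shaft_id": str},
                     float_precision="round_trip")
    _require_columns(df, CONTACT_COLUMNS, f"contacts file {path}")
    return [
        Contact(
            contact_id=str(r.contact_id),
            shaft_id=str(r.shaft_id),
            coord=np.array([r.x_mm, r.y_mm, r.z_mm], dtype=float),
            hemisphere=str(r.hemisphere),
            lobe=str(r.lobe),
            region="" if pd.isna(r.region) else str(r.region),
            is_soz=_parse_bool(r.is_soz),
            is_resected=_parse_bool(r.is_resected),
        )
        for r in df.itertuples()
    ]


def read_events(path) -> list[EventRecord]:
    """Read the events CSV (columns of :data:`EVENT_COLUMNS`)."""
    df = pd.read_csv(path, dtype={"contact_id": str},
                     float_precision="round_trip")
    _require_columns(df, EVENT_COLUMNS, f"events file {path}")
    return [
        EventRecord(
            contact_id=str(r.contact_id),
            onset_s=float(r.onset_s),
            category=str(r.category),
            peak_freq_hz=float(r.peak_freq_hz),
        )
        for r in df.itertuples()
    ]


def load_patient(electrodes_path, events_path, meta_path) -> PatientRecord:
    """Assemble and validate a :class:`PatientRecord` from its three files."""
    contacts = read_contacts(electrodes_path)
    events = read_events(events_path)
    with open(meta_path, encoding="utf-8") as fh:
        meta = json.load(fh)
    for key in ("patient_id", "duration_min"):
        if key not in meta:
            raise SchemaError(f"metadata {meta_path}: missing key {key!r}")
    rns = None
    if meta.get("rns"):
        rns = RNSLeads(
            stim_coords=np.asarray(meta["rns"]["stim_coords"], dtype=float),
            lead_types=tuple(meta["rns"].get("lead_types", ["depth", "depth"])),
        )
    return PatientRecord(
        patient_id=str(meta["patient_id"]),
        contacts=contacts,
        events=events,
        duration_min=float(meta["duration_min"]),
        engel=meta.get("engel"),
        rns=rns,
    )


def write_patient(patient: PatientRecord, out_dir) -> dict[str, Path]:
    """Write the three patient files; returns their paths.

    The on-disk representation round-trips exactly through
    :func:`load_patient` (coordinates and onsets use full float repr).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cpath = out / f"{patient.patient_id}_contacts.tsv"
    epath = out / f"{patient.patient_id}_events.csv"
    mpath = out / f"{patient.patient_id}_meta.json"
    cdf = pd.DataFrame(
        [
            (c.contact_id, c.shaft_id, *(repr(float(x)) for x in c.coord),
             c.hemisphere, c.lobe, c.region, c.is_soz, c.is_resected)
            for c in patient.contacts
        ],
        columns=CONTACT_COLUMNS,
    )
    cdf.to_csv(cpath, sep="\t", index=False)
    edf = pd.DataFrame(
        [(e.contact_id, repr(float(e.onset_s)), e.category, repr(float(e.peak_freq_hz)))
         for e in patient.events],
        columns=EVENT_COLUMNS,
    )
    edf.to_csv(epath, index=False)
    meta = {
        "patient_id": patient.patient_id,
        "duration_min": patient.duration_min,
        "engel": patient.engel,
    }
    if patient.rns is not None:
        meta["rns"] = {
            "stim_coords": patient.rns.stim_coords.tolist(),
            "lead_types": list(patient.rns.lead_types),
        }
    with open(mpath, "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1)
    return {"contacts": cpath, "events": epath, "meta": mpath}


def write_metrics_report(rows: Iterable[dict], path, summary: bool = True) -> pd.DataFrame:
    """Write a per-patient metrics table as CSV.

    Each row is a mapping of metric name to value (``None`` allowed).
    With ``summary=True`` a trailing ``mean`` and ``sem`` row pair is
    appended over the numeric columns (values as mean and standard error
    of the mean).
    """
    df = pd.DataFrame(list(rows))
    out = df.copy()
    if summary and len(df) > 1:
        num = df.select_dtypes(include=[np.number])
        mean_row = {c: num[c].mean() for c in num.columns}
        sem_row = {c: num[c].sem() for c in num.columns}
        label_col = df.columns[0]
        mean_row[label_col] = "mean"
        sem_row[label_col] = "sem"
        out = pd.concat(
            [df, pd.DataFrame([mean_row, sem_row])], ignore_index=True
        )
    out.to_csv(path, index=False, float_format="%.6f")
    return out
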