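"""Synthetic SEEG patients with the statistical structure the pipeline assumes.

Each synthetic patient is an implant of linear depth-electrode shafts in
a brain-sized bounding box (MNI-like millimetre coordinates, hemispheres
by the sign of x, lobes by a fixed geometric partition).  Fast-ripple
activity is planted in two tiers:

* an **autonomous core** — a small, spatially clustered set of contacts
  emitting independent high-rate (2-10/min) FR>350 Poisson trains: high
  rate, near-zero pairwise MI, low local efficiency;
* a **coupled halo** — a larger ring of contacts around the core whose
  FR trains are jittered (sigma = 20 ms) thinned copies (p_copy = 0.7)
  of shared latent Poisson trains: modest rates with high pairwise MI
  and high local efficiency.

Background ripples (RonS/RonO) occur everywhere.  The actual resection
is a sphere around the core centroid; in roughly half the cohort the
sphere center is displaced beyond its own radius to model surgeries
that miss the core.  The ground-truth outcome is seizure free exactly
when every core contact is resected.  The generated files use the standard contacts/events/metadata
formats, so synthetic patients are indistinguishable from real ones to
the rest of the pipeline.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from .data_model import Contact, EventRecord, PatientRecord

__all__ = ["SyntheticCohortConfig", "GroundTruth", "generate_patient",
           "generate_cohort"]

# brain-sized bounding box, MNI-like mm
_X_LIM = (-65.0, 65.0)
_Y_LIM = (-85.0, 55.0)
_Z_LIM = (-45.0, 65.0)


def lobe_of(coord: np.ndarray) -> str:
    """Fixed geometric lobe partition (enough for the three-lobe rule)."""
    _, y, z = coord
    if z < -10.0:
        return "temporal"
    if y > 15.0:
        return "frontal"
    if y < -55.0:
        return "occipital"
    return "parietal"


@dataclasses.dataclass(frozen=True)
class SyntheticCohortConfig:
    """Generator parameters; defaults emulate the target recordings."""

    n_patients: int = 18
    n_shafts: tuple[int, int] = (8, 16)
    contacts_per_shaft: tuple[int, int] = (7, 15)
    spacing_mm: float = 5.0
    duration_min: float = 30.0
    core_size: tuple[int, int] = (3, 6)
    core_rate_per_min: tuple[float, float] = (2.0, 10.0)
    halo_size: tuple[int, int] = (6, 12)
    latent_rate_per_min: float = 1.0
    p_copy: float = 0.7
    jitter_sd_ms: float = 20.0
    frons_fraction: float = 0.35
    background_rons_per_min: float = 0.3
    background_rono_per_min: float = 0.3
    resection_radius_mm: tuple[float, float] = (15.0, 25.0)
    #: displaced ("failed") resections shift the sphere center by the
    #: resection radius plus this margin, so part of the core is left in
    displacement_beyond_radius_mm: tuple[float, float] = (2.0, 10.0)
    displaced_fraction: float = 0.5
    label_flip_prob: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_copy <= 1.0:
            raise ValueError("p_copy must be in [0, 1]")
        for name in ("n_shafts", "contacts_per_shaft", "core_size",
                     "halo_size", "core_rate_per_min",
                     "resection_radius_mm", "displacement_beyond_radius_mm"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be a positive ordered range")


@dataclasses.dataclass
class GroundTruth:
    core_ids: list[str]
    halo_ids: list[str]
    core_centroid: np.ndarray
    resection_center: np.ndarray
    resection_radius_mm: float
    displaced: bool
    all_core_resected: bool
    seizure_free: bool


def _poisson_train(rate_per_min: float, duration_s: float,
                   rng: np.random.Generator) -> np.ndarray:
    n = rng.poisson(rate_per_min * duration_s / 60.0)
    return np.sort(rng.uniform(0.0, duration_s, n))


def _place_shafts(cfg: SyntheticCohortConfig, rng: np.random.Generator):
    """Linear shafts entering from the lateral surfaces."""
    n_shafts = int(rng.integers(cfg.n_shafts[0], cfg.n_shafts[1] + 1))
    contacts: list[tuple[str, str, np.ndarray]] = []
    for s in range(n_shafts):
        m = int(rng.integers(cfg.contacts_per_shaft[0],
                             cfg.contacts_per_shaft[1] + 1))
        side = 1.0 if rng.random() < 0.5 else -1.0
        entry = np.array([
            side * _X_LIM[1],
            rng.uniform(*_Y_LIM),
            rng.uniform(*_Z_LIM),
        ])
        direction = np.array([-side, rng.normal(0.0, 0.3), rng.normal(0.0, 0.3)])
        direction /= np.linalg.norm(direction)
        shaft_id = f"S{s:02d}"
        for k in range(m):
            coord = entry + k * cfg.spacing_mm * direction
            contacts.append((f"{shaft_id}-{k:02d}", shaft_id, coord))
    return contacts


def _jittered_copy(latent: np.ndarray, p_copy: float, jitter_s: float,
                   duration_s: float, rng: np.random.Generator) -> np.ndarray:
    keep = rng.random(latent.size) < p_copy
    t = latent[keep] + rng.normal(0.0, jitter_s, int(keep.sum()))
    return np.sort(np.clip(t, 0.0, duration_s))


def generate_patient(
    config: SyntheticCohortConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
    patient_id: Optional[str] = None,
    displaced: Optional[bool] = None,
) -> tuple[PatientRecord, GroundTruth]:
    """One synthetic patient plus its planted ground truth.

    ``displaced`` forces the resection-displacement arm (drawn with
    probability ``displaced_fraction`` when omitted).  Deterministic for
    a fixed seed.
    """
    cfg = config or SyntheticCohortConfig()
    rng = np.random.default_rng(seed)
    duration_s = cfg.duration_min * 60.0
    jitter_s = cfg.jitter_sd_ms / 1000.0

    for _attempt in range(10):
        placed = _place_shafts(cfg, rng)
        ids = [p[0] for p in placed]
        coords = np.array([p[2] for p in placed])
        hemi = np.where(coords[:, 0] >= 0, "R", "L")

        # autonomous core: nearest contacts to a random lateral seed
        interior = np.flatnonzero(np.abs(coords[:, 0]) > 15.0)
        if interior.size < cfg.core_size[1] + cfg.halo_size[1]:
            continue
        seed_idx = int(rng.choice(interior))
        same_hemi = np.flatnonzero(hemi == hemi[seed_idx])
        order = same_hemi[np.argsort(
            np.linalg.norm(coords[same_hemi] - coords[seed_idx], axis=1))]
        n_core = int(rng.integers(cfg.core_size[0], cfg.core_size[1] + 1))
        n_halo = int(rng.integers(cfg.halo_size[0], cfg.halo_size[1] + 1))
        if order.size < n_core + n_halo:
            continue
        core_idx = order[:n_core]
        halo_idx = order[n_core:n_core + n_halo]

        events: list[EventRecord] = []

        def fr_events(cid: str, train: np.ndarray) -> None:
            for t in train:
                if rng.random() < cfg.frons_fraction:
                    events.append(EventRecord(cid, float(t), "fRonS",
                                              float(rng.uniform(250.0, 550.0))))
                else:
                    events.append(EventRecord(cid, float(t), "fRonO",
                                              float(rng.uniform(360.0, 580.0))))

        for i in core_idx:
            rate = rng.uniform(*cfg.core_rate_per_min)
            fr_events(ids[i], _poisson_train(rate, duration_s, rng))

        latents = [_poisson_train(cfg.latent_rate_per_min, duration_s, rng)
                   for _ in range(2)]
        for pos, i in enumerate(halo_idx):
            latent = latents[pos % len(latents)]
            train = _jittered_copy(latent, cfg.p_copy, jitter_s, duration_s, rng)
            for t in train:
                events.append(EventRecord(ids[i], float(t), "fRonO",
                                          float(rng.uniform(360.0, 580.0))))

        for i, cid in enumerate(ids):
            for t in _poisson_train(cfg.background_rons_per_min, duration_s, rng):
                events.append(EventRecord(cid, float(t), "RonS",
                                          float(rng.uniform(90.0, 190.0))))
            for t in _poisson_train(cfg.background_rono_per_min, duration_s, rng):
                events.append(EventRecord(cid, float(t), "RonO",
                                          float(rng.uniform(90.0, 190.0))))

        centroid = coords[core_idx].mean(axis=0)
        if displaced is None:
            is_displaced = bool(rng.random() < cfg.displaced_fraction)
        else:
            is_displaced = bool(displaced)
        radius = rng.uniform(*cfg.resection_radius_mm)
        center = centroid.copy()
        if is_displaced:
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            shift = radius + rng.uniform(*cfg.displacement_beyond_radius_mm)
            center = centroid + shift * u
        core_hemi = hemi[core_idx[0]]
        resected = {
            ids[i] for i in range(len(ids))
            if hemi[i] == core_hemi
            and np.linalg.norm(coords[i] - center) <= radius
        }

        soz = {ids[i] for i in core_idx} | set(
            ids[i] for i in halo_idx[: max(1, n_halo // 3)]
        )
        contacts = [
            Contact(
                contact_id=ids[i], shaft_id=placed[i][1], coord=coords[i],
                hemisphere=str(hemi[i]), lobe=lobe_of(coords[i]),
                region=f"synthetic-{lobe_of(coords[i])}",
                is_soz=ids[i] in soz, is_resected=ids[i] in resected,
            )
            for i in range(len(ids))
        ]
        all_core_resected = all(ids[i] in resected for i in core_idx)
        seizure_free = all_core_resected
        if cfg.label_flip_prob > 0 and rng.random() < cfg.label_flip_prob:
            seizure_free = not seizure_free
        engel = "IA" if seizure_free else "IVB"
        n_fr_contacts = len({e.contact_id for e in events
                             if e.category in ("fRonO", "fRonS")})
        if n_fr_contacts < 2:
            continue
        patient = PatientRecord(
            patient_id=patient_id or f"SYN{int(rng.integers(0, 10**6)):06d}",
            contacts=contacts,
            events=sorted(events, key=lambda e: (e.onset_s, e.contact_id)),
            duration_min=cfg.duration_min,
            engel=engel,
        )
        gt = GroundTruth(
            core_ids=[ids[i] for i in core_idx],
            halo_ids=[ids[i] for i in halo_idx],
            core_centroid=centroid,
            resection_center=center,
            resection_radius_mm=float(radius),
            displaced=is_displaced,
            all_core_resected=all_core_resected,
            seizure_free=seizure_free,
        )
        return patient, gt
    raise RuntimeError("failed to generate a patient with >= 2 FR contacts")


def generate_cohort(
    config: SyntheticCohortConfig | None = None, seed: int = 0
) -> list[tuple[PatientRecord, GroundTruth]]:
    """A cohort with roughly balanced outcome labels.

    Alternates intact and displaced resections so about half the cohort
    fails to cover the core; the realized label balance varies because a
    small displacement can still cover a compact core.
    """
    cfg = config or SyntheticCohortConfig()
    if cfg.n_patients < 6:
        raise ValueError("n_patients must be >= 6")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(cfg.n_patients)
    cohort = []
    for k, child in enumerate(children):
        patient, gt = generate_patient(
            cfg, seed=child, patient_id=f"SYN{k:03d}", displaced=(k % 2 == 1)
        )
        cohort.append((patient, gt))
    return cohort
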