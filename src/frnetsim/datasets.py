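"""Bundled reference datasets.

Per-patient results from the 18-patient surgical reference cohort the
method was developed on: virtual-resection metrics (virtual and actual
resection radii, resection ratios, the four FR factors, overlap
fractions) and contact-level overlap statistics between virtual and
actual resections, split by post-operative outcome group.  These small
tables support desk-scale reproduction of the cohort summary statistics
without access to the original recordings.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "reference_virtual_resections",
    "reference_overlap",
]


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("frnetsim") / "data" / name
    with resources.as_file(ref) as path:
        return pd.read_csv(path, dtype={"patient_id": str})


def reference_virtual_resections(group: str = "seizure_free") -> pd.DataFrame:
    """Per-patient virtual-resection metrics for one outcome group.

    Parameters
    ----------
    group : {"seizure_free", "not_seizure_free"}
        The post-operative outcome group.  The not-seizure-free table
        carries a ``virtually_seizure_free`` column and leaves
        ``virtual_radius_mm`` empty for patients whose virtual resection
        never reached a seizure-free label.
    """
    if group not in ("seizure_free", "not_seizure_free"):
        raise ValueError(f"unknown group {group!r}")
    return _load(f"reference_virtual_resections_{group}.csv")


def reference_overlap(group: str = "seizure_free") -> pd.DataFrame:
    """Contact-level virtual-vs-actual overlap statistics for one group."""
    if group not in ("seizure_free", "not_seizure_free"):
        raise ValueError(f"unknown group {group!r}")
    return _load(f"reference_overlap_{group}.csv")
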