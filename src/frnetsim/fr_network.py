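"""Fast-ripple networks and the four outcome factors.

Two graphs are built per patient, both over the contacts that generate
FR>350 events (fast ripples on oscillations >350 Hz plus all fast
ripples on spikes):

* the **MI network** — a symmetric nonnegative adjacency of mutual
  information (bits) between the contacts' FR onset-time trains; edge
  lengths are the element-wise reciprocal of MI (no edge where MI = 0);
* the **rate-distance graph** — a complete graph whose edge weights are
  the mean FR>350 rate of the two contacts multiplied by their Euclidean
  distance in mm (or the distance alone), used for graph radii.

From these, four factors summarize a (real or virtual) resection:

fr_rr
    fraction of FR>350 events on resected contacts.
spatial_frnet
    sqrt of the drop in rate-distance graph radius when the graph is
    restricted to the resected FR nodes (0 when everything FR-generating
    is resected).
temporal_frnet_a
    characteristic path length of the resected MI subgraph over that of
    the whole MI network.
temporal_frnet_b
    mean nodal local efficiency over the unresected nodes with LE > 0
    (1.0, flagged degenerate, when no node qualifies).
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import csgraph_from_dense, shortest_path

from . import event_metrics
from .data_model import PatientRecord
from .mi import MIOptions, mi_between_trains

__all__ = [
    "MIGraph", "FRFeatureVector", "build_mi_graph", "local_efficiency",
    "characteristic_path_length", "global_efficiency", "graph_radius",
    "spatial_frnet", "temporal_frnet_a", "temporal_frnet_b", "feature_vector",
]


@dataclasses.dataclass
class MIGraph:
    """Symmetric MI adjacency over FR>350-generating contacts."""

    node_ids: list[str]
    adjacency: np.ndarray
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=float)
        n = len(self.node_ids)
        if a.shape != (n, n):
            raise ValueError("adjacency shape does not match node count")
        if np.any(a < 0):
            raise ValueError("MI adjacency must be nonnegative")
        if not np.allclose(a, a.T, atol=1e-12, rtol=0.0):
            raise ValueError("MI adjacency must be symmetric")
        np.fill_diagonal(a, 0.0)
        self.adjacency = a

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def lengths(self) -> np.ndarray:
        """Edge lengths 1/MI; infinity where MI = 0 (no edge)."""
        with np.errstate(divide="ignore"):
            L = np.where(self.adjacency > 0, 1.0 / self.adjacency, np.inf)
        np.fill_diagonal(L, 0.0)
        return L

    def index_of(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.node_ids)}
        return np.array([lookup[c] for c in ids if c in lookup], dtype=int)

    def to_edge_frame(self) -> pd.DataFrame:
        """Edge list (upper triangle, MI > 0) for CSV export."""
        rows = []
        L = self.lengths
        for i, j in itertools.combinations(range(self.n_nodes), 2):
            if self.adjacency[i, j] > 0:
                rows.append(
                    (self.node_ids[i], self.node_ids[j],
                     self.adjacency[i, j], L[i, j])
                )
        return pd.DataFrame(rows, columns=["node_a", "node_b", "mi_bits", "length"])

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.node_ids)
        for _, r in self.to_edge_frame().iterrows():
            g.add_edge(r.node_a, r.node_b, mi_bits=float(r.mi_bits),
                       length=float(r.length))
        return g

    def write_graphml(self, path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), path)


@dataclasses.dataclass(frozen=True)
class FRFeatureVector:
    """The four SVM factors for one (real or virtual) resection.

    Components that could not be computed (degenerate subgraphs) are
    ``None``; ``flags`` names them.
    """

    fr_rr: Optional[float]
    spatial_frnet: Optional[float]
    temporal_frnet_a: Optional[float]
    temporal_frnet_b: Optional[float]
    flags: tuple[str, ...] = ()

    def as_array(self) -> np.ndarray:
        """Length-4 float array with NaN for unavailable components."""
        return np.array(
            [np.nan if v is None else float(v)
             for v in (self.fr_rr, self.spatial_frnet,
                       self.temporal_frnet_a, self.temporal_frnet_b)]
        )


FEATURE_NAMES = ("fr_rr", "spatial_frnet", "temporal_frnet_a", "temporal_frnet_b")


def fr350_trains(patient: PatientRecord) -> dict[str, np.ndarray]:
    """Sorted FR>350 onset trains keyed by contact id (only contacts with >=1)."""
    trains: dict[str, list[float]] = {}
    for e in patient.events:
        if event_metrics.is_fr350(e):
            trains.setdefault(e.contact_id, []).append(e.onset_s)
    order = {c: i for i, c in enumerate(patient.contact_ids)}
    return {
        c: np.sort(np.asarray(trains[c], dtype=float))
        for c in sorted(trains, key=order.__getitem__)
    }


def build_mi_graph(
    patient: PatientRecord,
    opts: MIOptions | None = None,
    rates: pd.DataFrame | None = None,
) -> MIGraph:
    """All-pairs MI network over the FR>350-generating contacts.

    Flags carried on the graph:

    * ``"degenerate"`` — fewer than 2 FR-generating contacts; the
      patient cannot support network analysis.
    * ``"poor_spatial_sampling"`` — no contact generates fast ripples on
      spikes above 1/min (the implant is judged to have missed the
      epileptogenic network).
    * ``"disconnected"`` — every off-diagonal MI is zero.
    """
    opts = opts or MIOptions(duration_s=patient.duration_min * 60.0)
    if opts.duration_s is None:
        opts = dataclasses.replace(opts, duration_s=patient.duration_min * 60.0)
    trains = fr350_trains(patient)
    ids = list(trains)
    n = len(ids)
    flags: list[str] = []
    if n < 2:
        flags.append("degenerate")
    if rates is None:
        rates = event_metrics.contact_rates(patient)
    frons_per_min = {}
    for e in patient.events:
        if e.category == "fRonS":
            frons_per_min[e.contact_id] = frons_per_min.get(e.contact_id, 0) + 1
    if not any(v / patient.duration_min > 1.0 for v in frons_per_min.values()):
        flags.append("poor_spatial_sampling")
    adj = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        adj[i, j] = adj[j, i] = mi_between_trains(trains[ids[i]], trains[ids[j]], opts)
    if n >= 2 and not np.any(adj > 0):
        flags.append("disconnected")
    return MIGraph(node_ids=ids, adjacency=adj, flags=tuple(flags))


def _subgraph_distances(lengths: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path distances within the induced subgraph."""
    sub = lengths[np.ix_(idx, idx)]
    return shortest_path(sub, method="D", directed=False)


def local_efficiency(g: MIGraph, node: str | int) -> float:
    """Weighted nodal local efficiency.

    Efficiency of the subgraph induced by the node's neighbors, with the
    adjacency first normalized by its global maximum so that a complete
    graph of equal weights has LE exactly 1.  Nodes with fewer than two
    neighbors have LE 0.
    """
    i = g.node_ids.index(node) if isinstance(node, str) else int(node)
    wmax = g.adjacency.max()
    if wmax <= 0:
        return 0.0
    W = g.adjacency / wmax
    nbrs = np.flatnonzero(W[i] > 0)
    if nbrs.size < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        L = np.where(W > 0, 1.0 / W, np.inf)
    np.fill_diagonal(L, 0.0)
    d = _subgraph_distances(L, nbrs)
    k = nbrs.size
    off = ~np.eye(k, dtype=bool)
    inv = np.zeros_like(d)
    np.divide(1.0, d, out=inv, where=np.isfinite(d) & (d > 0))
    return float(inv[off].mean())


def nodal_local_efficiency(g: MIGraph) -> pd.Series:
    """Local efficiency of every node, indexed by contact id."""
    return pd.Series(
        [local_efficiency(g, i) for i in range(g.n_nodes)],
        index=g.node_ids, name="local_efficiency",
    )


def characteristic_path_length(
    g: MIGraph, subset: Iterable[str] | None = None
) -> tuple[Optional[float], int]:
    """Mean shortest-path length over ordered pairs in the induced subgraph.

    Pairs with no finite path are excluded from the mean; their count is
    returned alongside.  Returns ``(None, 0)`` for subsets of fewer than
    two nodes.
    """
    idx = (np.arange(g.n_nodes) if subset is None else g.index_of(subset))
    if idx.size < 2:
        return None, 0
    d = _subgraph_distances(g.lengths, idx)
    off = ~np.eye(idx.size, dtype=bool)
    vals = d[off]
    finite = np.isfinite(vals)
    n_inf = int((~finite).sum())
    if not finite.any():
        return None, n_inf
    return float(vals[finite].mean()), n_inf


def global_efficiency(g: MIGraph, subset: Iterable[str] | None = None) -> Optional[float]:
    """Mean inverse shortest-path length over ordered pairs (0 when disconnected).

    Computed on the raw 1/MI lengths, so a direct edge contributes its
    MI.  ``None`` for subsets of fewer than two nodes.
    """
    idx = (np.arange(g.n_nodes) if subset is None else g.index_of(subset))
    if idx.size < 2:
        return None
    d = _subgraph_distances(g.lengths, idx)
    off = ~np.eye(idx.size, dtype=bool)
    inv = np.zeros_like(d)
    np.divide(1.0, d, out=inv, where=np.isfinite(d) & (d > 0))
    return float(inv[off].mean())


def graph_radius(
    patient: PatientRecord,
    nodes: Sequence[str],
    weight_rule: str = "rate_distance",
    rates: pd.DataFrame | None = None,
) -> Optional[float]:
    """Radius (min eccentricity) of the complete weighted graph on ``nodes``.

    Edge weights: Euclidean distance in mm, optionally multiplied by the
    arithmetic mean of the two contacts' FR>350 rates
    (``weight_rule="rate_distance"``).  Weights act directly as path
    lengths and shortest paths may route through intermediate nodes.
    A single node has radius 0; an empty set returns ``None``.
    """
    nodes = list(nodes)
    if not nodes:
        return None
    if len(nodes) == 1:
        return 0.0
    coords = np.array([patient.contact(c).coord for c in nodes])
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))
    if weight_rule == "rate_distance":
        if rates is None:
            rates = event_metrics.contact_rates(patient)
        r = rates.loc[nodes, "fr350"].to_numpy()
        w = 0.5 * (r[:, None] + r[None, :]) * dist
    elif weight_rule == "distance_only":
        w = dist
    else:
        raise ValueError(f"unknown weight rule {weight_rule!r}")
    np.fill_diagonal(w, 0.0)
    # zero-weight edges between distinct nodes are legitimate (rate 0):
    # keep them as explicit zeros rather than letting dense conversion
    # drop them as non-edges
    d = shortest_path(csgraph_from_dense(w, null_value=np.inf),
                      method="D", directed=False)
    ecc = d.max(axis=1)
    return float(ecc.min())


def _fr_nodes(patient: PatientRecord, rates: pd.DataFrame) -> list[str]:
    return [c for c in patient.contact_ids if rates.loc[c, "fr350"] > 0]


def spatial_frnet(
    patient: PatientRecord,
    resected: Iterable[str],
    rates: pd.DataFrame | None = None,
) -> Optional[float]:
    """Rate-distance-radius resected difference (mm^0.5-scaled, >= 0).

    sqrt(max(0, R_whole - R_resected)) where both radii use the
    rate-distance rule over FR>350-generating nodes.  Resecting every
    FR-generating node gives exactly 0; a resection containing no FR
    node leaves the resected-only radius at 0.  ``None`` when the
    patient has no FR-generating nodes.
    """
    if rates is None:
        rates = event_metrics.contact_rates(patient)
    fr_nodes = _fr_nodes(patient, rates)
    if not fr_nodes:
        return None
    resected = set(resected)
    r_whole = graph_radius(patient, fr_nodes, "rate_distance", rates)
    res_nodes = [c for c in fr_nodes if c in resected]
    r_res = graph_radius(patient, res_nodes, "rate_distance", rates) or 0.0
    return float(np.sqrt(max(0.0, r_whole - r_res)))


def temporal_frnet_a(g: MIGraph, resected: Iterable[str]) -> Optional[float]:
    """Path-length resection ratio: CPL(resected subgraph) / CPL(whole network).

    ``None`` (feature unavailable) when either path length is undefined
    or the whole-network path length is not finite and positive.
    """
    num, _ = characteristic_path_length(g, resected)
    den, _ = characteristic_path_length(g, None)
    if num is None or den is None or not np.isfinite(den) or den <= 0:
        return None
    return float(num / den)


def temporal_frnet_b(
    g: MIGraph, resected: Iterable[str], scope: str = "unresected"
) -> tuple[float, bool]:
    """Mean nodal local efficiency over qualifying (LE > 0) nodes.

    ``scope="unresected"`` (default) evaluates the nodes left in place
    by the resection — the quantity the virtual simulator must respond
    to; ``scope="all"`` evaluates every node.  Returns ``(value,
    degenerate)``; when no evaluated node has LE > 0 the value is the
    degenerate convention 1.0.
    """
    resected = set(resected)
    if scope == "unresected":
        eval_nodes = [c for c in g.node_ids if c not in resected]
    elif scope == "all":
        eval_nodes = list(g.node_ids)
    else:
        raise ValueError(f"unknown scope {scope!r}")
    le = [local_efficiency(g, c) for c in eval_nodes]
    pos = [v for v in le if v > 0]
    if not pos:
        return 1.0, True
    return float(np.mean(pos)), False


def feature_vector(
    patient: PatientRecord,
    resected: Iterable[str],
    graph: MIGraph | None = None,
    rates: pd.DataFrame | None = None,
    frnet_b_scope: str = "unresected",
) -> FRFeatureVector:
    """The four outcome factors for a given resected contact set."""
    resected = set(resected)
    if rates is None:
        rates = event_metrics.contact_rates(patient)
    if graph is None:
        graph = build_mi_graph(patient, rates=rates)
    flags: list[str] = []
    fr_rr = event_metrics.event_resection_ratio(patient, "fr350", resected)
    if fr_rr is None:
        flags.append("fr_rr_undefined")
    sp = spatial_frnet(patient, resected, rates)
    if sp is None:
        flags.append("spatial_frnet_undefined")
    ta = temporal_frnet_a(graph, resected)
    if ta is None:
        flags.append("temporal_frnet_a_undefined")
    tb, degenerate = temporal_frnet_b(graph, resected, scope=frnet_b_scope)
    if degenerate:
        flags.append("temporal_frnet_b_degenerate")
    return FRFeatureVector(
        fr_rr=fr_rr, spatial_frnet=sp, temporal_frnet_a=ta,
        temporal_frnet_b=tb, flags=tuple(flags),
    )
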