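"""Cohort-level statistics: nonparametric tests, autonomy clustering, and
trial power calculations.

The exact Wilcoxon signed-rank test enumerates the full signed-rank null
(all 2^n sign assignments, midranks for tied magnitudes) for n <= 15 and
falls back to the tie-corrected normal approximation above that.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans

__all__ = [
    "StudyDesign", "kruskal_wallis", "wilcoxon_signrank_exact",
    "autonomy_clusters", "two_proportion_power", "enrollment_inflation",
]

EXACT_ENUMERATION_MAX_N = 15


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p (k-1 df)."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group must be nonempty")
    allv = np.concatenate(arrays)
    if np.all(allv == allv[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def wilcoxon_signrank_exact(
    pairs: Iterable[tuple[float, float]]
) -> tuple[float, float]:
    """Exact two-sided Wilcoxon signed-rank test on paired values.

    Differences are first - second; zero differences are dropped.
    Returns (W+, p) where W+ is the positive-rank sum.  The p-value is
    the doubled one-sided exact tail (capped at 1), from enumeration of
    every sign assignment when n <= 15.
    """
    d = np.array([float(a) - float(b) for a, b in pairs])
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_ENUMERATION_MAX_N:
        # distribution of W+ over all 2^n sign vectors
        totals = np.zeros(1)
        for r in ranks:
            totals = np.concatenate([totals, totals + r])
        p_le = np.mean(totals <= w_plus + 1e-9)
        p_ge = np.mean(totals >= w_plus - 1e-9)
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        _, p = stats.wilcoxon(d, alternative="two-sided", method="approx")
        p = float(p)
    return w_plus, p


def autonomy_clusters(
    log_rates: Sequence[float],
    le: Sequence[float],
    k: int = 2,
    seed: int = 0,
    n_init: int = 10,
) -> tuple[np.ndarray, int]:
    """K-means clustering of nodes in (log FR rate, local efficiency) space.

    Features are z-scored before clustering (unit-free axes), and the
    *autonomous* cluster is the one with the lowest mean local
    efficiency.  Deterministic under a fixed seed.

    Returns (labels, autonomous_cluster_id).
    """
    X = np.column_stack([
        np.asarray(log_rates, dtype=float), np.asarray(le, dtype=float)
    ])
    if not np.all(np.isfinite(X)):
        raise ValueError("log_rates and le must be finite")
    if np.unique(X, axis=0).shape[0] < k:
        raise ValueError(f"fewer than k={k} distinct points")
    sd = X.std(axis=0)
    Z = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(Z)
    le_arr = X[:, 1]
    means = [le_arr[labels == c].mean() for c in range(k)]
    return labels, int(np.argmin(means))


def unresected_autonomous_count(
    patient, graph, rates, resected: Optional[set] = None,
    k: int = 2, seed: int = 0,
) -> int:
    """Number of autonomous-cluster MI-network nodes left unresected.

    Clusters the patient's FR>350-generating nodes on (log natural rate,
    local efficiency) and counts autonomous-cluster nodes outside the
    resected set (defaults to the actual resection).
    """
    from . import fr_network

    if resected is None:
        resected = patient.resected_set
    nodes = list(graph.node_ids)
    if len(nodes) < k:
        return 0
    log_rate = np.log(rates.loc[nodes, "fr350"].to_numpy())
    le = fr_network.nodal_local_efficiency(graph).loc[nodes].to_numpy()
    try:
        labels, auto = autonomy_clusters(log_rate, le, k=k, seed=seed)
    except ValueError:
        return 0
    return int(sum(1 for c, lab in zip(nodes, labels)
                   if lab == auto and c not in resected))


@dataclasses.dataclass(frozen=True)
class StudyDesign:
    """Two-arm trial design for a seizure-freedom endpoint."""

    p_control: float
    p_active: float
    n_per_arm: int
    alpha: float = 0.05
    dropout_control: float = 0.0
    dropout_active: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p_control", "p_active"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.n_per_arm < 2:
            raise ValueError("n_per_arm must be >= 2")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


def two_proportion_power(design: StudyDesign) -> float:
    """Power of the two-sided unpooled-variance Z-test for two proportions.

    power = Phi(|d|/SE - z) + Phi(-|d|/SE - z), with
    SE = sqrt(p1 q1 / n + p2 q2 / n) and z the upper alpha/2 normal
    quantile.
    """
    p1, p2, n = design.p_control, design.p_active, design.n_per_arm
    se = math.sqrt(p1 * (1 - p1) / n + p2 * (1 - p2) / n)
    z = stats.norm.ppf(1.0 - design.alpha / 2.0)
    delta = abs(p2 - p1) / se
    return float(stats.norm.cdf(delta - z) + stats.norm.cdf(-delta - z))


def enrollment_inflation(n_per_arm: int, dropout: float) -> int:
    """Enrollment needed so n_per_arm complete after a dropout fraction."""
    if not 0.0 <= dropout < 1.0:
        raise ValueError("dropout must be in [0, 1)")
    return int(math.ceil(n_per_arm / (1.0 - dropout)))
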