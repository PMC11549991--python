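"""Density thresholding, centrality, AUC summaries, hubs and ranks.

Network properties depend on density, so metrics are computed over a
sweep of proportional thresholds (default 5%..80% in 5% steps, 16
levels) and summarised per node by the plain sum across densities
("AUC"), a threshold-free summary. Hubs are nodes whose AUC exceeds the
across-node mean plus one standard deviation.

Betweenness centrality treats edge length as the reciprocal of the
connection weight — in streamline-weighted connectomes larger weight
means stronger connection, so shortest paths should prefer strong edges
(the Brain Connectivity Toolbox convention). Eigenvector centrality is
the entrywise-nonnegative leading eigenvector of the weight matrix,
scaled to unit Euclidean norm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import igraph as ig
import numpy as np
from scipy.stats import rankdata

from .io import Connectome

METRICS = ("BC", "EC")


@dataclass(frozen=True)
class DensitySweep:
    """Ordered network densities, default 0.05..0.80 step 0.05."""

    densities: tuple[float, ...] = tuple(np.round(np.arange(1, 17) * 0.05, 2))

    def __post_init__(self) -> None:
        d = np.asarray(self.densities, dtype=float)
        if len(d) == 0 or np.any(d <= 0) or np.any(d > 1):
            raise ValueError("densities must lie in (0, 1]")
        if np.any(np.diff(d) <= 0):
            raise ValueError("densities must be strictly increasing")

    def __len__(self) -> int:
        return len(self.densities)


def threshold_by_density(c: Connectome, density: float) -> Connectome:
    """Keep the ``ceil(density * n(n-1)/2)`` largest-weight edges.

    Kept edges retain their weights; everything else is zeroed. Ties are
    broken by (row, column) lexicographic order so the retained edge set
    is nested across densities.
    """
    if not (0.0 < density <= 1.0):
        raise ValueError(f"density must lie in (0, 1], got {density}")
    n = c.n_nodes
    k = ceil(density * n * (n - 1) / 2)
    iu = np.triu_indices(n, k=1)
    w = c.weights[iu]
    pos = np.flatnonzero(w > 0)
    if len(pos) > k:
        # stable sort on -weight; upper-triangle flattening is already
        # (row, column) lexicographic, so ties resolve deterministically
        order = pos[np.argsort(-w[pos], kind="stable")]
        keep = order[:k]
    else:
        keep = pos
    out = np.zeros((n, n))
    out[iu[0][keep], iu[1][keep]] = w[keep]
    out = out + out.T
    return Connectome(out, c.atlas, c.subject_id)


def _igraph_from(weights: np.ndarray) -> tuple[ig.Graph, list[float]]:
    n = weights.shape[0]
    iu = np.triu_indices(n, k=1)
    mask = weights[iu] > 0
    edges = list(zip(iu[0][mask].tolist(), iu[1][mask].tolist()))
    g = ig.Graph(n=n, edges=edges)
    lengths = (1.0 / weights[iu][mask]).tolist()
    return g, lengths


def betweenness_centrality(c: Connectome | np.ndarray) -> np.ndarray:
    """Weighted betweenness: shortest-path counts through each node.

    Path length of an edge is the reciprocal of its weight; ties between
    equal-length geodesics are counted fractionally and path endpoints
    are excluded. Unreachable pairs contribute zero.
    """
    w = c.weights if isinstance(c, Connectome) else np.asarray(c, dtype=float)
    g, lengths = _igraph_from(w)
    if g.ecount() == 0:
        return np.zeros(w.shape[0])
    return np.asarray(g.betweenness(weights=lengths, directed=False), dtype=float)


def eigenvector_centrality(
    c: Connectome | np.ndarray, return_eigenvalue: bool = False
):
    """Leading eigenvector of the weight matrix, unit Euclidean norm.

    A node scores high when its connections lead to other high-scoring
    nodes: the centrality vector satisfies ``W v = lambda v`` with
    ``lambda`` the largest eigenvalue. On a disconnected network the
    vector concentrates on the dominant component.
    """
    w = c.weights if isinstance(c, Connectome) else np.asarray(c, dtype=float)
    if not np.any(w):
        raise ValueError("eigenvector centrality undefined for an all-zero matrix")
    vals, vecs = np.linalg.eigh(w)
    lam = vals[-1]
    v = vecs[:, -1]
    if v.sum() < 0:
        v = -v
    v = np.where(np.abs(v) < 1e-15, 0.0, v)  # clean numerical dust
    if return_eigenvalue:
        return v, float(lam)
    return v


def centrality_over_sweep(
    c: Connectome, metric: str, sweep: DensitySweep | None = None
) -> np.ndarray:
    """Node x density matrix of the metric over the thresholded networks."""
    if sweep is None:
        sweep = DensitySweep()
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")
    fn = betweenness_centrality if metric == "BC" else eigenvector_centrality
    cols = [fn(threshold_by_density(c, d)) for d in sweep.densities]
    return np.column_stack(cols)


def auc(values: np.ndarray) -> np.ndarray:
    """Threshold-free summary: plain (unweighted) sum across densities."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty value matrix")
    if v.ndim == 1:
        v = v[:, None]
    return v.sum(axis=1)


def identify_hubs(auc_values: np.ndarray) -> np.ndarray:
    """Nodes whose AUC strictly exceeds mean + 1 sample SD (ddof=1)."""
    v = np.asarray(auc_values, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 nodes")
    cutoff = v.mean() + v.std(ddof=1)
    return np.flatnonzero(v > cutoff)


def hub_ranks(auc_values: np.ndarray) -> np.ndarray:
    """Rank 1 = largest value; ties get the mean of the tied ranks."""
    v = np.asarray(auc_values, dtype=float)
    return rankdata(-v, method="average")


@dataclass(frozen=True)
class CentralityProfile:
    """One subject's centrality over the sweep plus its summaries."""

    metric: str
    values: np.ndarray  # node x density
    auc: np.ndarray
    normalized_auc: np.ndarray  # auc / mean(auc), mean exactly 1
    hubs: np.ndarray  # node indices
    ranks: np.ndarray  # 1 = highest AUC


def centrality_profile(
    c: Connectome, metric: str, sweep: DensitySweep | None = None
) -> CentralityProfile:
    values = centrality_over_sweep(c, metric, sweep)
    a = auc(values)
    return CentralityProfile(
        metric=metric,
        values=values,
        auc=a,
        normalized_auc=a / a.mean(),
        hubs=identify_hubs(a),
        ranks=hub_ranks(a),
    )
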