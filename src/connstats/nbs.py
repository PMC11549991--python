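"""Network-based statistics: edge-wise GLM contrasts with nuisance
covariates, supra-threshold component extraction, and permutation
family-wise-error inference.

Each of the 3,321 unique edges is fit by ordinary least squares on
(intercept, group indicator, age, sex, ICV); the one-tailed group
contrast gives an edge-wise t-statistic. Edges with t above a primary
threshold form a graph whose connected components are candidate effects;
the size (edge count) of the largest observed component is compared with
its distribution under random relabeling of the group indicator
(covariates stay attached to their subjects), which controls the
family-wise error rate over all edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components as _sp_components

from .io import CohortTable, Connectome


@dataclass(frozen=True)
class DesignMatrix:
    """Design for one two-group, one-tailed edge-wise contrast.

    ``x`` has columns (intercept, group indicator, age, sex, icv) over the
    subjects of the two tested groups; ``contrast`` selects the group
    column with its direction (+1: first group mean larger).
    """

    x: np.ndarray
    contrast: np.ndarray
    group_col: int
    subject_index: np.ndarray  # positions into the cohort's connectome list

    def __post_init__(self) -> None:
        if np.linalg.matrix_rank(self.x) < self.x.shape[1]:
            raise ValueError("design matrix is rank deficient")


def build_design(
    cohort: CohortTable,
    group_a: str,
    group_b: str,
    direction: int = +1,
    covariates: tuple[str, ...] = ("age", "sex", "icv"),
) -> DesignMatrix:
    """Contrast ``group_a`` vs ``group_b``; direction +1 tests a > b."""
    df = cohort.table
    mask = df["group"].isin([group_a, group_b]).to_numpy()
    sub = df[mask]
    n = len(sub)
    indicator = (sub["group"] == group_a).to_numpy(dtype=float)
    cols = [np.ones(n), indicator] + [sub[c].to_numpy(dtype=float) for c in covariates]
    x = np.column_stack(cols)
    contrast = np.zeros(x.shape[1])
    contrast[1] = float(np.sign(direction) or 1)
    return DesignMatrix(
        x=x,
        contrast=contrast,
        group_col=1,
        subject_index=np.flatnonzero(mask),
    )


def stack_edge_data(connectomes: list[Connectome]) -> np.ndarray:
    """Subjects x edges matrix of upper-triangle weights."""
    return np.vstack([c.upper_values() for c in connectomes])


def _glm_t(y: np.ndarray, x: np.ndarray, contrast: np.ndarray) -> np.ndarray:
    """Vectorised OLS t-statistics for one contrast over many responses."""
    n, p = x.shape
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y
    resid = y - x @ beta
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    # residual variance at round-off level (e.g. identical responses) is
    # genuinely zero: the edge carries no evidence and gets t = 0
    scale = (y**2).mean(axis=0)
    degenerate = sigma2 <= scale * 1e-18
    c_var = float(contrast @ xtx_inv @ contrast)
    se = np.sqrt(c_var * sigma2)
    est = contrast @ beta
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, est / np.where(se > 0, se, 1.0), 0.0)
    t[degenerate] = 0.0
    return t


def edgewise_glm_t(
    connectomes: list[Connectome], design: DesignMatrix
) -> np.ndarray:
    """Symmetric matrix of edge-wise contrast t-statistics.

    Edges with zero residual variance get t = 0 (no evidence either way).
    """
    y = stack_edge_data([connectomes[i] for i in design.subject_index])
    t_flat = _glm_t(y, design.x, design.contrast)
    n = connectomes[0].n_nodes
    t = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    t[iu] = t_flat
    return t + t.T


@dataclass(frozen=True)
class Component:
    nodes: tuple[int, ...]
    edges: tuple[tuple[int, int], ...]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def supra_threshold_components(
    t_matrix: np.ndarray, primary_threshold: float
) -> list[Component]:
    """Connected components of the graph of edges with t > threshold.

    Sorted by edge count, largest first. Isolated nodes are not
    components; an empty list means no edge survived.
    """
    if primary_threshold <= 0:
        raise ValueError("primary threshold must be positive")
    n = t_matrix.shape[0]
    adj = np.triu(t_matrix > primary_threshold, k=1)
    ii, jj = np.nonzero(adj)
    if len(ii) == 0:
        return []
    g = csr_matrix((np.ones(len(ii)), (ii, jj)), shape=(n, n))
    n_comp, labels = _sp_components(g, directed=False)
    comps: dict[int, list[tuple[int, int]]] = {}
    for i, j in zip(ii.tolist(), jj.tolist()):
        comps.setdefault(labels[i], []).append((i, j))
    out = []
    for edges in comps.values():
        nodes = tuple(sorted({v for e in edges for v in e}))
        out.append(Component(nodes=nodes, edges=tuple(edges)))
    out.sort(key=lambda comp: (-comp.n_edges, comp.nodes))
    return out


def _max_component_size(t_flat: np.ndarray, threshold: float, n: int, iu) -> int:
    mask = t_flat > threshold
    k = int(mask.sum())
    if k == 0:
        return 0
    g = csr_matrix(
        (np.ones(k), (iu[0][mask], iu[1][mask])), shape=(n, n)
    )
    _, labels = _sp_components(g, directed=False)
    sizes = np.bincount(labels[iu[0][mask]], minlength=0)
    # count edges per component via the label of one endpoint
    edge_labels = labels[iu[0][mask]]
    return int(np.bincount(edge_labels).max())


@dataclass(frozen=True)
class NBSResult:
    t_matrix: np.ndarray
    primary_threshold: float
    components: list[Component]
    p_fwe: np.ndarray  # per component, same order
    max_component_size: int
    null_max_sizes: np.ndarray
    n_perm: int
    exhaustive: bool
    seed: int


def _null_indicator_draws(
    n: int, n_a: int, n_perm: int, rng: np.random.Generator
) -> tuple[np.ndarray, bool]:
    """Group-indicator relabelings: exhaustive when feasible, else random.

    Returns (n_draws x n) 0/1 matrix and whether it enumerates all
    distinct relabelings (including the observed one).
    """
    total = comb(n, n_a)
    if n_perm >= total:
        draws = np.zeros((total, n))
        for r, idx in enumerate(combinations(range(n), n_a)):
            draws[r, list(idx)] = 1.0
        return draws, True
    draws = np.zeros((n_perm, n))
    for r in range(n_perm):
        idx = rng.choice(n, size=n_a, replace=False)
        draws[r, idx] = 1.0
    return draws, False


def nbs_test(
    connectomes: list[Connectome],
    design: DesignMatrix,
    primary_threshold: float,
    n_perm: int = 5000,
    seed: int = 0,
) -> NBSResult:
    """Permutation FWE test on supra-threshold component size (edge count).

    ``p_fwe`` of each observed component is the fraction of relabelings
    whose maximum component is at least as large; with random sampling
    the observed labeling is included, giving
    ``(1 + #{null >= obs}) / (n_perm + 1)``. When ``n_perm`` meets or
    exceeds the number of distinct relabelings the null is enumerated
    exhaustively and p is exact.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = stack_edge_data([connectomes[i] for i in design.subject_index])
    n_nodes = connectomes[0].n_nodes
    iu = np.triu_indices(n_nodes, k=1)

    t_flat = _glm_t(y, design.x, design.contrast)
    t_full = np.zeros((n_nodes, n_nodes))
    t_full[iu] = t_flat
    t_full = t_full + t_full.T
    components = supra_threshold_components(t_full, primary_threshold)
    obs_max = components[0].n_edges if components else 0

    rng = np.random.default_rng(seed)
    n = design.x.shape[0]
    n_a = int(design.x[:, design.group_col].sum())
    draws, exhaustive = _null_indicator_draws(n, n_a, n_perm, rng)

    null_sizes = np.empty(len(draws), dtype=int)
    x_perm = design.x.copy()
    for r, indicator in enumerate(draws):
        x_perm[:, design.group_col] = indicator
        t_r = _glm_t(y, x_perm, design.contrast)
        null_sizes[r] = _max_component_size(t_r, primary_threshold, n_nodes, iu)

    p_fwe = np.empty(len(components))
    for k, compnt in enumerate(components):
        exceed = int((null_sizes >= compnt.n_edges).sum())
        if exhaustive:
            p_fwe[k] = exceed / len(draws)
        else:
            p_fwe[k] = (1 + exceed) / (len(draws) + 1)

    return NBSResult(
        t_matrix=t_full,
        primary_threshold=primary_threshold,
        components=components,
        p_fwe=p_fwe,
        max_component_size=obs_max,
        null_max_sizes=null_sizes,
        n_perm=len(draws),
        exhaustive=exhaustive,
        seed=seed,
    )


def threshold_sweep_report(
    connectomes: list[Connectome],
    design: DesignMatrix,
    thresholds: list[float] | None = None,
    n_perm: int = 5000,
    seed: int = 0,
) -> pd.DataFrame:
    """One row per primary threshold: nodes, edges and FWE p of the
    largest component; dashes when no edge survives the threshold."""
    if thresholds is None:
        thresholds = [round(2.1 + 0.1 * k, 1) for k in range(10)]
    if not thresholds:
        raise ValueError("threshold list is empty")
    rows = []
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(len(thresholds))]
    for thr, s in zip(thresholds, child_seeds):
        res = nbs_test(connectomes, design, thr, n_perm=n_perm, seed=s)
        if res.components:
            comp = res.components[0]
            rows.append(
                {
                    "threshold": thr,
                    "nodes": comp.n_nodes,
                    "edges": comp.n_edges,
                    "p": res.p_fwe[0],
                }
            )
        else:
            rows.append({"threshold": thr, "nodes": None, "edges": None, "p": None})
    return pd.DataFrame(rows)
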