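"""Module (community) detection: modularity partitions, balanced
subsampling, and iterated consensus clustering across subjects.

The common module structure of a cohort is found by running a seeded
Louvain-style modularity optimisation many times on each subject's
network, pooling all partitions into a node-by-node co-assignment
("consensus") matrix, and re-clustering that matrix iteratively until
every run agrees. Balanced subsampling (equal numbers per group) avoids
biasing the consensus towards the largest group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph as ig
import leidenalg as la
import numpy as np

from .io import GROUPS, CohortTable, Connectome


@dataclass(frozen=True)
class Partition:
    """Assignment of nodes to modules, ids contiguous from 1."""

    assignment: np.ndarray  # int module id per node, 1..n_modules

    def __post_init__(self) -> None:
        a = np.asarray(self.assignment, dtype=int)
        ids = np.unique(a)
        if len(a) == 0:
            raise ValueError("empty partition")
        if not np.array_equal(ids, np.arange(1, len(ids) + 1)):
            # canonicalise: relabel by order of first appearance
            remap = {}
            out = np.empty_like(a)
            for i, m in enumerate(a):
                if m not in remap:
                    remap[m] = len(remap) + 1
                out[i] = remap[m]
            a = out
        a.flags.writeable = False
        object.__setattr__(self, "assignment", a)

    @property
    def n_nodes(self) -> int:
        return len(self.assignment)

    @property
    def n_modules(self) -> int:
        return int(self.assignment.max())

    @property
    def module_sizes(self) -> np.ndarray:
        return np.bincount(self.assignment)[1:]

    def members(self, module_id: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == module_id)

    @staticmethod
    def from_membership(membership) -> "Partition":
        """From a 0-based membership list (igraph convention)."""
        return Partition(np.asarray(membership, dtype=int) + 1)


@dataclass(frozen=True)
class ConsensusConfig:
    """Parameters of the iterated consensus-clustering procedure.

    n_runs
        Modularity-optimisation repetitions per subject network.
    tau
        Consensus-matrix entries below this co-assignment fraction are
        zeroed before re-clustering.
    gamma
        Modularity resolution parameter.
    max_iter
        Cap on consensus iterations.
    """

    n_runs: int = 100
    tau: float = 0.4
    gamma: float = 1.0
    max_iter: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if not (0.0 < self.tau < 1.0):
            raise ValueError("tau must lie in (0, 1)")


@dataclass(frozen=True)
class ConsensusResult:
    partition: Partition
    consensus_matrix: np.ndarray  # first-iteration co-assignment fractions
    n_iter: int
    converged: bool


def balanced_subsample(cohort: CohortTable, k_per_group: int, seed: int) -> list[str]:
    """Draw ``k_per_group`` subject ids from each group without replacement.

    Reproducible from ``seed``; groups are visited in canonical order and
    selected ids keep their cohort-table order.
    """
    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    for group in GROUPS:
        ids = [
            sid
            for sid, g in zip(cohort.subject_ids, cohort.groups)
            if g == group
        ]
        if len(ids) < k_per_group:
            raise ValueError(
                f"group {group} has {len(ids)} subjects, need {k_per_group}"
            )
        pick = rng.choice(len(ids), size=k_per_group, replace=False)
        chosen.extend(ids[i] for i in sorted(pick))
    return chosen


def _weighted_graph(weights: np.ndarray) -> ig.Graph:
    n = weights.shape[0]
    iu = np.triu_indices(n, k=1)
    mask = weights[iu] > 0
    edges = list(zip(iu[0][mask].tolist(), iu[1][mask].tolist()))
    g = ig.Graph(n=n, edges=edges)
    g.es["weight"] = weights[iu][mask].tolist()
    return g


def modularity_partition(
    c: Connectome | np.ndarray, gamma: float = 1.0, seed: int = 0
) -> Partition:
    """One greedy weighted-modularity partition at resolution ``gamma``."""
    w = c.weights if isinstance(c, Connectome) else np.asarray(c, dtype=float)
    if w.size == 0:
        raise ValueError("empty graph")
    g = _weighted_graph(w)
    part = la.find_partition(
        g,
        la.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=gamma,
        seed=int(seed),
    )
    return Partition.from_membership(part.membership)


def coassignment_matrix(partitions: list[Partition]) -> np.ndarray:
    """Fraction of partitions placing each node pair in the same module."""
    n = partitions[0].n_nodes
    m = np.zeros((n, n))
    for p in partitions:
        a = p.assignment
        m += (a[:, None] == a[None, :]).astype(float)
    m /= len(partitions)
    return m


def _expected_coassignment(partitions: list[Partition]) -> float:
    """Permutation-expected co-assignment rate of a set of partitions.

    For one partition, the chance that two distinct nodes land together
    under random relabeling is sum n_c (n_c - 1) / (n (n - 1)); the rate
    is averaged over partitions.
    """
    n = partitions[0].n_nodes
    rates = []
    for p in partitions:
        sizes = p.module_sizes.astype(float)
        rates.append((sizes * (sizes - 1)).sum() / (n * (n - 1)))
    return float(np.mean(rates))


def consensus_partition(
    connectomes: list[Connectome], config: ConsensusConfig
) -> ConsensusResult:
    """Iterated consensus clustering pooled over subjects and runs.

    Each subject network is partitioned ``n_runs`` times; all partitions
    are pooled into one co-assignment matrix, which is thresholded at
    ``tau``, corrected by subtracting the permutation-expected
    co-assignment rate, and re-clustered until all runs agree (the
    co-assignment matrix is binary) or ``max_iter`` is hit.
    """
    if not connectomes:
        raise ValueError("need at least one connectome")
    rng = np.random.default_rng(config.seed)

    def run_many(weight_matrices: list[np.ndarray]) -> list[Partition]:
        parts = []
        for w in weight_matrices:
            for _ in range(config.n_runs):
                s = int(rng.integers(0, 2**31 - 1))
                parts.append(modularity_partition(w, gamma=config.gamma, seed=s))
        return parts

    partitions = run_many([c.weights for c in connectomes])
    consensus0 = coassignment_matrix(partitions)
    consensus = consensus0
    converged = False
    n_iter = 0
    while n_iter < config.max_iter:
        n_iter += 1
        binary = np.all((consensus == 0.0) | (consensus == 1.0))
        if binary:
            converged = True
            break
        d = consensus.copy()
        d[d < config.tau] = 0.0
        p_exp = _expected_coassignment(partitions)
        d = np.clip(d - p_exp, 0.0, None)
        np.fill_diagonal(d, 0.0)
        partitions = run_many([d])
        consensus = coassignment_matrix(partitions)
    final = partitions[-1]
    if not converged:
        warnings.warn(
            f"consensus clustering did not converge in {config.max_iter} "
            "iterations; returning the last partition",
            RuntimeWarning,
        )
    return ConsensusResult(
        partition=final,
        consensus_matrix=consensus0,
        n_iter=n_iter,
        converged=converged,
    )


def module_mean(values: np.ndarray, partition: Partition) -> np.ndarray:
    """Arithmetic mean of node-wise values within each module.

    ``values`` is (n_nodes,) or (n_subjects, n_nodes); the module axis
    replaces the node axis in the result.
    """
    v = np.asarray(values, dtype=float)
    a = partition.assignment
    if v.shape[-1] != len(a):
        raise ValueError("values do not cover all nodes")
    out = np.empty(v.shape[:-1] + (partition.n_modules,))
    for m in range(1, partition.n_modules + 1):
        idx = np.flatnonzero(a == m)
        if idx.size == 0:
            raise ValueError(f"module {m} is empty")
        out[..., m - 1] = v[..., idx].mean(axis=-1)
    return out
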