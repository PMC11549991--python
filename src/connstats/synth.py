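"""Synthetic connectome cohorts with known ground truth.

Emulates SIFT2-weighted 82-node structural connectomes: a modular block
structure (stronger within- than between-module weights), a small set of
hub nodes whose connections are globally strengthened, multiplicative
log-normal edge noise (streamline-weight sums are positive and
right-skewed), covariates (age, sex, intracranial volume) with ICV acting
as a global multiplicative nuisance on all weights, and a planted
group-specific reduction of a connected edge set in the sustained-exposure
group (PAE_T1T3). The no-exposure and first-trimester groups share the
null generative model, so every downstream stage — covariate-adjusted
edge statistics, module detection, hub extraction — has a known answer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .atlas import Atlas, build_atlas
from .community import Partition
from .io import GROUPS, CohortTable, Connectome
import pandas as pd

#: Per-group ICV mean and SD in cm^3 (study-cohort demographics).
ICV_BY_GROUP: dict[str, tuple[float, float]] = {
    "noPAE": (1556.0, 139.4),
    "PAE_T1": (1519.0, 128.9),
    "PAE_T1T3": (1613.0, 121.5),
}

AGE_RANGE = (6.8, 7.8)  # years
ICV_REF = 1550.0  # cm^3; weights scale as (icv / ICV_REF) ** icv_exponent


def default_partition(n_nodes: int = 82, n_modules: int = 11) -> Partition:
    """Planted modules with sizes as even as possible (8 x 5 + 7 x 6 for 82)."""
    base = n_nodes // n_modules
    extra = n_nodes % n_modules
    sizes = [base + 1] * extra + [base] * (n_modules - extra)
    assignment = np.repeat(np.arange(1, n_modules + 1), sizes)
    return Partition(assignment)


def default_hubs(partition: Partition, n_hubs: int = 7) -> tuple[int, ...]:
    """One hub per module for the first ``n_hubs`` modules."""
    return tuple(int(partition.members(m)[0]) for m in range(1, n_hubs + 1))


def default_effect_edges(partition: Partition, n_edges: int = 20) -> tuple[tuple[int, int], ...]:
    """A connected edge set inside module 1 (lexicographic upper-triangle order)."""
    nodes = partition.members(1)
    edges = []
    for a in range(len(nodes)):
        for b in range(a + 1, len(nodes)):
            edges.append((int(nodes[a]), int(nodes[b])))
            if len(edges) == n_edges:
                return tuple(edges)
    raise ValueError(
        f"module 1 has only {len(edges)} internal edges, need {n_edges}"
    )


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative parameters of a synthetic cohort.

    Defaults are the package's reference study conditions: 82 nodes in 11
    modules, 7 hub nodes, within/between block weights 1.0/0.15,
    hub strength factor 2.0, 25% log-normal edge noise, and a 30% weight
    reduction on a connected 20-edge set in the PAE_T1T3 group.
    """

    n_nodes: int = 82
    partition_true: Partition = field(default_factory=default_partition)
    hub_nodes: tuple[int, ...] = ()
    base_within: float = 1.0
    base_between: float = 0.15
    hub_boost: float = 2.0
    effect_edges: tuple[tuple[int, int], ...] = ()
    effect_size: float = 0.3
    noise_cv: float = 0.25
    icv_exponent: float = 1.0

    def __post_init__(self) -> None:
        if self.partition_true.n_nodes != self.n_nodes:
            raise ValueError("planted partition does not cover n_nodes")
        if not (0.0 <= self.effect_size < 1.0):
            raise ValueError("effect_size must lie in [0, 1)")
        if self.base_within <= 0 or self.base_between <= 0:
            raise ValueError("base weights must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be nonnegative")
        if not self.hub_nodes:
            object.__setattr__(self, "hub_nodes", default_hubs(self.partition_true))
        if not self.effect_edges and self.effect_size > 0:
            object.__setattr__(
                self, "effect_edges", default_effect_edges(self.partition_true)
            )
        for i, j in self.effect_edges:
            if not (0 <= i < j < self.n_nodes):
                raise ValueError(f"effect edge ({i}, {j}) not in upper triangle")
        if self.base_between >= self.base_within:
            warnings.warn(
                "base_between >= base_within: planted modules are "
                "undetectable by construction",
                UserWarning,
            )


def base_weight_matrix(spec: SyntheticSpec) -> np.ndarray:
    """Noise-free expected weight matrix: blocks plus hub strengthening."""
    a = spec.partition_true.assignment
    same = a[:, None] == a[None, :]
    w = np.where(same, spec.base_within, spec.base_between)
    boost = np.ones(spec.n_nodes)
    boost[list(spec.hub_nodes)] = spec.hub_boost
    w = w * boost[:, None] * boost[None, :]
    np.fill_diagonal(w, 0.0)
    return w


def generate_base_connectome(
    spec: SyntheticSpec,
    rng: np.random.Generator,
    atlas: Atlas | None = None,
    subject_id: str = "synthetic",
) -> Connectome:
    """One subject's network: block structure, hubs, log-normal edge noise.

    The multiplicative noise has mean 1 and coefficient of variation
    ``noise_cv``, so expected weights equal the noise-free block matrix.
    """
    if atlas is None:
        atlas = _atlas_for(spec.n_nodes)
    w = base_weight_matrix(spec)
    if spec.noise_cv > 0:
        sigma2 = np.log1p(spec.noise_cv**2)
        mu = -sigma2 / 2.0
        iu = np.triu_indices(spec.n_nodes, k=1)
        noise = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=len(iu[0]))
        full = np.zeros_like(w)
        full[iu] = noise
        full = full + full.T
        w = w * full
    return Connectome(w, atlas, subject_id)


def _atlas_for(n_nodes: int) -> Atlas:
    if n_nodes == 82:
        return build_atlas()
    labels = tuple(f"L.N{i:03d}" for i in range(n_nodes))
    return Atlas(labels=labels, hemisphere=("L",) * n_nodes)


@dataclass(frozen=True)
class SyntheticCohort:
    connectomes: list[Connectome]
    cohort: CohortTable
    truth: SyntheticSpec

    def __post_init__(self) -> None:
        if len(self.connectomes) != len(self.cohort):
            raise ValueError("connectome list and cohort table sizes differ")


def generate_cohort(
    spec: SyntheticSpec,
    n_per_group: tuple[int, int, int] = (24, 30, 36),
    seed: int = 0,
) -> SyntheticCohort:
    """Generate a three-group cohort with the planted group difference.

    PAE_T1T3 subjects have the effect-edge weights multiplied by
    ``1 - effect_size``; the other two groups share the null model.
    Covariates: age ~ U(6.8, 7.8) years, sex ~ Bernoulli(1/2) (1 =
    female), ICV ~ N(per-group mean, SD) cm^3; every subject's weights
    are scaled by ``(icv / 1550) ** icv_exponent`` so that ICV is a real
    nuisance the covariate adjustment must remove.
    """
    if any(n < 2 for n in n_per_group):
        raise ValueError("need at least 2 subjects per group")
    rng = np.random.default_rng(seed)
    atlas = _atlas_for(spec.n_nodes)
    rows = []
    connectomes: list[Connectome] = []
    sub = 0
    for group, n in zip(GROUPS, n_per_group):
        icv_mean, icv_sd = ICV_BY_GROUP[group]
        for _ in range(n):
            sub += 1
            sid = f"sub-{sub:03d}"
            age = float(rng.uniform(*AGE_RANGE))
            sex = int(rng.integers(0, 2))
            icv = float(rng.normal(icv_mean, icv_sd))
            conn = generate_base_connectome(spec, rng, atlas=atlas, subject_id=sid)
            w = np.array(conn.weights)
            if group == "PAE_T1T3" and spec.effect_size > 0:
                for i, j in spec.effect_edges:
                    w[i, j] *= 1.0 - spec.effect_size
                    w[j, i] = w[i, j]
            w *= (icv / ICV_REF) ** spec.icv_exponent
            connectomes.append(Connectome(w, atlas, sid))
            rows.append(
                {"subject_id": sid, "group": group, "age": age, "sex": sex, "icv": icv}
            )
    cohort = CohortTable(pd.DataFrame(rows))
    return SyntheticCohort(connectomes=connectomes, cohort=cohort, truth=spec)


def planted_truth_report(cohort: SyntheticCohort) -> dict:
    """Machine-readable ground truth for recovery tests."""
    spec = cohort.truth
    part = spec.partition_true
    return {
        "n_nodes": spec.n_nodes,
        "n_modules": part.n_modules,
        "modules": [part.members(m).tolist() for m in range(1, part.n_modules + 1)],
        "hub_nodes": list(spec.hub_nodes),
        "effect_edges": [list(e) for e in spec.effect_edges]
        if spec.effect_size > 0
        else [],
        "effect_size": spec.effect_size if spec.effect_size > 0 else 0.0,
        "affected_group": "PAE_T1T3" if spec.effect_size > 0 else None,
    }
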