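"""End-to-end orchestration: load or synthesize a cohort, detect the
common module structure, run the centrality sweep, extract hubs, run the
NBS threshold sweep and the covariate-adjusted group tests at every
level, and write all reports plus a provenance manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import build_atlas, write_atlas
from .community import ConsensusConfig, Partition, balanced_subsample, consensus_partition, module_mean
from .io import GROUPS, CohortTable, Connectome, read_cohort, read_connectome, write_cohort, write_connectome
from .metrics import METRICS, DensitySweep, auc, centrality_over_sweep, hub_ranks, identify_hubs
from .nbs import build_design, threshold_sweep_report
from .stats import ancova_table
from .synth import SyntheticCohort, SyntheticSpec, generate_cohort, planted_truth_report

log = logging.getLogger("connstats")


@dataclass
class PipelineConfig:
    """Everything one analysis run needs; every stochastic stage derives
    its seed deterministically from ``seed``."""

    out_dir: str = "connstats_out"
    seed: int = 0
    # input: either a directory of matrices + cohort CSV, or synthetic
    connectome_dir: str | None = None
    cohort_csv: str | None = None
    synthetic: bool = True
    n_per_group: tuple[int, int, int] = (24, 30, 36)
    effect_size: float = 0.3
    # analysis parameters
    density_min: float = 0.05
    density_max: float = 0.80
    density_step: float = 0.05
    nbs_thresholds: tuple[float, ...] = tuple(round(2.1 + 0.1 * k, 1) for k in range(10))
    n_perm: int = 5000
    k_per_group: int = 24
    consensus_runs: int = 100
    consensus_tau: float = 0.4
    consensus_gamma: float = 1.0
    fdr_q: float = 0.05

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = PipelineConfig()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key: {key}")
            if isinstance(getattr(cfg, key), tuple) and value is not None:
                value = tuple(value)
            setattr(cfg, key, value)
        return cfg

    def sweep(self) -> DensitySweep:
        n = int(round((self.density_max - self.density_min) / self.density_step)) + 1
        return DensitySweep(
            tuple(round(self.density_min + k * self.density_step, 10) for k in range(n))
        )


@dataclass
class ResultBundle:
    config: PipelineConfig
    cohort: CohortTable
    partition: Partition
    auc_by_metric: dict[str, np.ndarray]  # subjects x nodes
    hub_tables: dict[str, pd.DataFrame]
    nbs_reports: dict[str, pd.DataFrame]
    ancova_tables: dict[str, pd.DataFrame]
    truth: dict | None = None


def _stage_seeds(master: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(n)]


def _load_inputs(config: PipelineConfig) -> tuple[list[Connectome], CohortTable, dict | None]:
    if config.synthetic:
        spec = SyntheticSpec(effect_size=config.effect_size)
        cohort = generate_cohort(spec, config.n_per_group, seed=_stage_seeds(config.seed, 1)[0])
        return cohort.connectomes, cohort.cohort, planted_truth_report(cohort)
    if not (config.connectome_dir and config.cohort_csv):
        raise ValueError("non-synthetic run needs connectome_dir and cohort_csv")
    cohort = read_cohort(config.cohort_csv)
    atlas = build_atlas()
    conns = [
        read_connectome(Path(config.connectome_dir) / f"{sid}.txt", atlas, sid)
        for sid in cohort.subject_ids
    ]
    return conns, cohort, None


def run_pipeline(config: PipelineConfig) -> ResultBundle:
    """Run every stage in order and write all reports under ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed, 5)
    stage = "load"
    try:
        connectomes, cohort, truth = _load_inputs(config)
        atlas = connectomes[0].atlas
        write_atlas(atlas, out / "atlas.tsv")
        write_cohort(cohort, out / "cohort.csv")
        if truth is not None:
            (out / "truth.json").write_text(json.dumps(truth, indent=2))
        log.info("loaded %d subjects (%s)", len(cohort), cohort.group_sizes())

        stage = "consensus_modules"
        ids = balanced_subsample(cohort, config.k_per_group, seed=seeds[0])
        idx = {s: i for i, s in enumerate(cohort.subject_ids)}
        subsample = [connectomes[idx[s]] for s in ids]
        cons = consensus_partition(
            subsample,
            ConsensusConfig(
                n_runs=config.consensus_runs,
                tau=config.consensus_tau,
                gamma=config.consensus_gamma,
                seed=seeds[1],
            ),
        )
        partition = cons.partition
        pd.DataFrame(
            {"label": atlas.labels, "module": partition.assignment}
        ).to_csv(out / "modules.tsv", sep="\t", index=False)
        np.savetxt(out / "consensus_matrix.txt", cons.consensus_matrix, fmt="%.6g")
        log.info("consensus: %d modules (converged=%s)", partition.n_modules, cons.converged)

        stage = "centrality_sweep"
        sweep = config.sweep()
        auc_by_metric: dict[str, np.ndarray] = {}
        for metric in METRICS:
            rows = [auc(centrality_over_sweep(c, metric, sweep)) for c in connectomes]
            mat = np.vstack(rows)
            auc_by_metric[metric] = mat
            pd.DataFrame(mat, index=cohort.subject_ids, columns=atlas.labels).to_csv(
                out / f"auc_{metric.lower()}.csv"
            )

        stage = "hubs"
        hub_tables: dict[str, pd.DataFrame] = {}
        for metric in METRICS:
            mat = auc_by_metric[metric]
            for group in GROUPS:
                mask = (cohort.groups == group).to_numpy()
                if not mask.any():
                    continue
                group_auc = mat[mask].mean(axis=0)
                hubs = set(identify_hubs(group_auc).tolist())
                tbl = pd.DataFrame(
                    {
                        "label": atlas.labels,
                        "auc": group_auc,
                        "normalized_auc": group_auc / group_auc.mean(),
                        "is_hub": [i in hubs for i in range(atlas.n_nodes)],
                        "rank": hub_ranks(group_auc),
                    }
                ).sort_values("normalized_auc", ascending=False)
                key = f"{metric}_{group}"
                hub_tables[key] = tbl
                tbl.to_csv(out / f"hubs_{metric.lower()}_{group}.tsv", sep="\t", index=False)

        stage = "nbs"
        nbs_reports: dict[str, pd.DataFrame] = {}
        contrasts = [
            ("noPAE", "PAE_T1T3", +1),
            ("noPAE", "PAE_T1", +1),
            ("PAE_T1", "PAE_T1T3", +1),
        ]
        for ci, (ga, gb, direction) in enumerate(contrasts):
            design = build_design(cohort, ga, gb, direction)
            rep = threshold_sweep_report(
                connectomes,
                design,
                list(config.nbs_thresholds),
                n_perm=config.n_perm,
                seed=seeds[2] + ci,
            )
            key = f"{ga}_gt_{gb}" if direction > 0 else f"{ga}_lt_{gb}"
            nbs_reports[key] = rep
            rep.to_csv(out / f"nbs_{key}.csv", index=False)

        stage = "ancova"
        ancova_tables: dict[str, pd.DataFrame] = {}
        for metric in METRICS:
            mat = auc_by_metric[metric]
            levels = {
                "global": (mat.mean(axis=1, keepdims=True), ["whole_brain"]),
                "module": (
                    module_mean(mat, partition),
                    [f"module_{m}" for m in range(1, partition.n_modules + 1)],
                ),
                "node": (mat, list(atlas.labels)),
            }
            # hub level: ranks of nodes identified as hubs in every group
            hub_sets = [
                set(identify_hubs(mat[(cohort.groups == g).to_numpy()].mean(axis=0)).tolist())
                for g in GROUPS
                if (cohort.groups == g).any()
            ]
            common = sorted(set.intersection(*hub_sets)) if hub_sets else []
            if common:
                ranks = np.vstack([hub_ranks(row) for row in mat])
                levels["hub"] = (ranks[:, common], [atlas.labels[i] for i in common])
            for level, (vals, labels) in levels.items():
                ancova_tables[f"{metric}_{level}"] = ancova_table(
                    vals, cohort, labels, q=config.fdr_q
                )
                ancova_tables[f"{metric}_{level}"].to_csv(
                    out / f"ancova_{metric.lower()}_{level}.csv", index=False
                )

        stage = "manifest"
        cfg_dict = asdict(config)
        manifest = {
            "package": "connstats",
            "version": __version__,
            "config": cfg_dict,
            "config_sha256": hashlib.sha256(
                json.dumps(cfg_dict, sort_keys=True, default=str).encode()
            ).hexdigest(),
            "stage_seeds": seeds,
            "n_subjects": len(cohort),
            "n_modules": partition.n_modules,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    return ResultBundle(
        config=config,
        cohort=cohort,
        partition=partition,
        auc_by_metric=auc_by_metric,
        hub_tables=hub_tables,
        nbs_reports=nbs_reports,
        ancova_tables=ancova_tables,
        truth=truth,
    )


def make_report(bundle: ResultBundle) -> str:
    """Human-readable summary: NBS table per contrast, per-group hub
    lists in descending normalized-AUC order, module table, ANCOVA."""
    lines: list[str] = []
    lines.append("== Network-based statistics (largest component per threshold) ==")
    for name, rep in bundle.nbs_reports.items():
        lines.append(f"-- contrast {name} --")
        lines.append("threshold  nodes  edges  p")
        for _, row in rep.iterrows():
            nodes = "-" if pd.isna(row["nodes"]) else f"{int(row['nodes'])}"
            edges = "-" if pd.isna(row["edges"]) else f"{int(row['edges'])}"
            p = "-" if pd.isna(row["p"]) else f"{row['p']:.4f}"
            lines.append(f"{row['threshold']:<9.1f}  {nodes:>5}  {edges:>5}  {p}")
    lines.append("")
    lines.append("== Modules ==")
    sizes = bundle.partition.module_sizes
    lines.append(
        f"{bundle.partition.n_modules} modules, sizes: "
        + ", ".join(str(s) for s in sizes)
    )
    lines.append("")
    for key, tbl in bundle.hub_tables.items():
        hubs = tbl[tbl["is_hub"]]
        lines.append(
            f"hubs[{key}] ({len(hubs)}): "
            + ", ".join(f"{r.label} ({r.normalized_auc:.2f})" for r in hubs.itertuples())
        )
    lines.append("")
    lines.append("== Covariate-adjusted group tests (FDR within level) ==")
    for key, tbl in bundle.ancova_tables.items():
        n_sig = int(tbl["significant"].sum())
        lines.append(f"{key}: {len(tbl)} units, {n_sig} significant after FDR")
        for _, row in tbl[tbl["significant"]].iterrows():
            lines.append(
                f"    {row['unit']}: F={row['F']:.2f} p={row['p']:.4f} p_fdr={row['p_fdr']:.4f}"
            )
    return "\n".join(lines)
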