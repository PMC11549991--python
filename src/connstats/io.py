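"""Connectome and cohort containers plus plain-text readers/writers.

A connectome is one subject's symmetric nonnegative weighted adjacency
matrix over the atlas nodes (weights are SIFT2-style streamline-weight
sums, unitless). The exchange format is a dense square numeric matrix,
whitespace- or comma-delimited, one row per line, no header, node order =
atlas order. The cohort table is a CSV with header
``subject_id,group,age,sex,icv`` (sex coded 0/1, female = 1; icv in cm3).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import Atlas

GROUPS = ("noPAE", "PAE_T1", "PAE_T1T3")

#: Asymmetry below this is treated as writer round-off and silently
#: symmetrized; anything larger is rejected as genuinely directed input.
SYMMETRY_TOL = 1e-8


class ConnectomeError(ValueError):
    """Invalid connectome matrix (dimension, sign, symmetry or content)."""


class CohortError(ValueError):
    """Invalid cohort table (groups, duplicates or missing fields)."""


@dataclass(frozen=True)
class Connectome:
    """One subject's weighted structural network."""

    weights: np.ndarray
    atlas: Atlas
    subject_id: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ConnectomeError(f"weights must be square, got shape {w.shape}")
        if w.shape[0] != self.atlas.n_nodes:
            raise ConnectomeError(
                f"matrix is {w.shape[0]}x{w.shape[0]} but atlas has "
                f"{self.atlas.n_nodes} nodes"
            )
        if not np.all(np.isfinite(w)):
            i, j = np.argwhere(~np.isfinite(w))[0]
            raise ConnectomeError(f"non-finite weight at cell ({i}, {j})")
        neg = np.argwhere(w < 0)
        if neg.size:
            i, j = neg[0]
            raise ConnectomeError(f"negative weight {w[i, j]} at cell ({i}, {j})")
        asym = np.abs(w - w.T).max()
        if asym > SYMMETRY_TOL:
            i, j = np.unravel_index(np.abs(w - w.T).argmax(), w.shape)
            raise ConnectomeError(
                f"matrix asymmetric by {asym:.3g} at cell ({i}, {j})"
            )
        w = (w + w.T) / 2.0
        np.fill_diagonal(w, 0.0)
        w.flags.writeable = False
        object.__setattr__(self, "weights", w)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        """Count of nonzero upper-triangle edges."""
        iu = np.triu_indices(self.n_nodes, k=1)
        return int(np.count_nonzero(self.weights[iu]))

    def upper_values(self) -> np.ndarray:
        """Upper-triangle weights as a flat vector (fixed edge order)."""
        iu = np.triu_indices(self.n_nodes, k=1)
        return self.weights[iu]


def read_connectome(path: str | Path, atlas: Atlas, subject_id: str = "") -> Connectome:
    """Read and validate one delimited square matrix file."""
    path = Path(path)
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip().replace(",", " ")
            if not line:
                continue
            try:
                rows.append([float(tok) for tok in line.split()])
            except ValueError as exc:
                raise ConnectomeError(
                    f"{path.name}: non-numeric content on line {lineno}: {exc}"
                ) from exc
    n = len(rows)
    if any(len(r) != n for r in rows):
        raise ConnectomeError(f"{path.name}: rows of unequal length (not square)")
    if not subject_id:
        subject_id = path.stem
    return Connectome(np.asarray(rows, dtype=float), atlas, subject_id)


def write_connectome(conn: Connectome, path: str | Path) -> None:
    """Write the weight matrix as whitespace-delimited text (repr precision)."""
    np.savetxt(path, conn.weights, fmt="%.17g")


@dataclass(frozen=True)
class CohortTable:
    """Subject ids, group labels and covariates for the design matrix.

    ``table`` has columns subject_id, group, age, sex, icv; one row per
    subject, subject ids unique, group one of :data:`GROUPS`.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["subject_id", "group", "age", "sex", "icv"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise CohortError(f"cohort table missing columns: {missing}")
        df = self.table[required].copy()
        if df.isna().any().any():
            raise CohortError("cohort table has missing values")
        unknown = set(df["group"]) - set(GROUPS)
        if unknown:
            raise CohortError(f"unknown group label(s): {sorted(unknown)}")
        dup = df["subject_id"][df["subject_id"].duplicated()]
        if len(dup):
            raise CohortError(f"duplicate subject_id(s): {sorted(set(dup))}")
        df["subject_id"] = df["subject_id"].astype(str)
        df["age"] = df["age"].astype(float)
        df["sex"] = df["sex"].astype(int)
        df["icv"] = df["icv"].astype(float)
        object.__setattr__(self, "table", df.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.table)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.table["subject_id"])

    @property
    def groups(self) -> pd.Series:
        return self.table["group"]

    def group_sizes(self) -> dict[str, int]:
        counts = self.table["group"].value_counts()
        return {g: int(counts.get(g, 0)) for g in GROUPS}

    def subset(self, subject_ids: list[str]) -> "CohortTable":
        """Rows for the given subjects, in the given order."""
        df = self.table.set_index("subject_id").loc[subject_ids].reset_index()
        return CohortTable(df)


def read_cohort(path: str | Path) -> CohortTable:
    """Read and validate a cohort CSV with the fixed header."""
    df = pd.read_csv(path)
    return CohortTable(df)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    cohort.table.to_csv(path, index=False)
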