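"""The 82-region cortical + subcortical atlas used as the node set.

Nodes are the 41 Desikan-Killiany cortical regions plus subcortical
gray-matter structures (cerebellum excluded), one per hemisphere, giving
82 network nodes. Labels are ``L.<ABBR>`` / ``R.<ABBR>``; the node order
is all left-hemisphere regions (alphabetical by region name) followed by
all right-hemisphere regions in the same order. This order is a package
convention shared by every connectome in a cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

# (abbreviation, full region name), alphabetical by region name
REGIONS: tuple[tuple[str, str], ...] = (
    ("AC", "accumbens"),
    ("AM", "amygdala"),
    ("BSTS", "banks of superior temporal sulcus"),
    ("CACG", "caudal anterior cingulate gyrus"),
    ("CMFG", "caudal middle frontal gyrus"),
    ("CA", "caudate"),
    ("CU", "cuneus"),
    ("EC", "entorhinal cortex"),
    ("FP", "frontal pole"),
    ("FG", "fusiform gyrus"),
    ("HI", "hippocampus"),
    ("IPG", "inferior parietal gyrus"),
    ("ITG", "inferior temporal gyrus"),
    ("IN", "insula"),
    ("ICG", "isthmus cingulate gyrus"),
    ("LOG", "lateral occipital gyrus"),
    ("LOFG", "lateral orbito frontal gyrus"),
    ("LG", "lingual gyrus"),
    ("MOFG", "medial orbito frontal gyrus"),
    ("MTG", "middle temporal gyrus"),
    ("PA", "pallidum"),
    ("PaCG", "paracentral gyrus"),
    ("PHIG", "parahippocampal gyrus"),
    ("POP", "pars opercularis"),
    ("POR", "pars orbitalis"),
    ("PTR", "pars triangularis"),
    ("PCAL", "pericalcarine cortex"),
    ("PoCG", "postcentral gyrus"),
    ("PCG", "posterior cingulate gyrus"),
    ("PrCG", "precentral gyrus"),
    ("PCU", "precuneus"),
    ("PU", "putamen"),
    ("RACG", "rostral anterior cingulate gyrus"),
    ("RMFG", "rostral middle frontal gyrus"),
    ("SFG", "superior frontal gyrus"),
    ("SPG", "superior parietal gyrus"),
    ("STG", "superior temporal gyrus"),
    ("SMG", "supra marginal gyrus"),
    ("TP", "temporal pole"),
    ("TH", "thalamus proper"),
    ("TTG", "transverse temporal gyrus"),
)


@dataclass(frozen=True)
class Atlas:
    """An ordered node set: region labels plus per-node hemisphere flags."""

    labels: tuple[str, ...]
    hemisphere: tuple[str, ...]  # 'L' or 'R' per node

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.hemisphere):
            raise ValueError("labels and hemisphere flags differ in length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("atlas labels must be unique")
        bad = set(self.hemisphere) - {"L", "R"}
        if bad:
            raise ValueError(f"hemisphere flags must be 'L'/'R', got {bad}")

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        """Number of unique (upper-triangle) node pairs."""
        n = self.n_nodes
        return n * (n - 1) // 2

    def index(self, label: str) -> int:
        return self.labels.index(label)


def build_atlas() -> Atlas:
    """Build the canonical 82-node atlas (41 regions x 2 hemispheres).

    Deterministic: left-hemisphere regions first, right second, each in
    the fixed alphabetical region order of :data:`REGIONS`.
    """
    labels = tuple(f"{h}.{abbr}" for h in ("L", "R") for abbr, _ in REGIONS)
    hemis = tuple(h for h in ("L", "R") for _ in REGIONS)
    return Atlas(labels=labels, hemisphere=hemis)


def write_atlas(atlas: Atlas, path: str | Path) -> None:
    """Write the atlas as a two-column TSV (label, hemisphere) for provenance."""
    with open(path, "w") as fh:
        for lab, hemi in zip(atlas.labels, atlas.hemisphere):
            fh.write(f"{lab}\t{hemi}\n")


def read_atlas(path: str | Path) -> Atlas:
    labels, hemis = [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            lab, hemi = line.split("\t")
            labels.append(lab)
            hemis.append(hemi)
    return Atlas(labels=tuple(labels), hemisphere=tuple(hemis))
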