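"""Hierarchical marker-gene selection by credible-interval separation.

Within each level of the cell-type hierarchy, every ordered pair of
sibling nodes is interrogated: genes are ranked by the separation of their
95% credible intervals (lower bound of the putative marker's interval
minus upper bound of the other type's), only positive separations are
eligible, and the top k genes per pair are kept — by default 5, 10 and 20
at levels 1, 2 and 3, favouring markers of broad compartments as well as
of specific activation states. The union over all pairs, with full
provenance, is the signature gene list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .abundance import PosteriorSummary
from .hierarchy import CellHierarchy

__all__ = [
    "MarkerConfig",
    "MarkerList",
    "pairwise_rank",
    "select_markers",
    "build_signature_matrix",
]

PROVENANCE_COLUMNS = ["gene", "level", "winner", "loser", "gap"]


@dataclass
class MarkerConfig:
    k_per_level: dict[int, int] = field(default_factory=lambda: {1: 5, 2: 10, 3: 20})
    min_gap: float = 0.0

    def validate(self) -> None:
        if any(k < 1 for k in self.k_per_level.values()):
            raise ValueError("all k_per_level values must be >= 1")


@dataclass
class MarkerList:
    """Union of selected marker genes plus per-selection provenance."""

    provenance: pd.DataFrame  # columns: gene, level, winner, loser, gap

    @property
    def genes(self) -> list[str]:
        return sorted(self.provenance["gene"].unique())

    def provenance_of(self, gene: str) -> pd.DataFrame:
        return self.provenance[self.provenance["gene"] == gene]

    def markers_for(self, winner: str) -> list[str]:
        sub = self.provenance[self.provenance["winner"] == winner]
        return sorted(sub["gene"].unique())

    def to_tsv(self, path: str | Path) -> None:
        self.provenance.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MarkerList":
        return cls(pd.read_csv(path, sep="\t"))


def pairwise_rank(
    posterior: PosteriorSummary,
    type_a: str,
    type_b: str,
    min_gap: float = 0.0,
) -> pd.DataFrame:
    """Genes ranked by how credibly ``type_a`` exceeds ``type_b``.

    Returns a frame with columns gene, gap sorted by descending gap
    (ties broken lexicographically by gene); only gaps > ``min_gap`` are
    retained.
    """
    if len(posterior.table) == 0:
        raise ValueError("empty posterior")
    fa = posterior.frame_for(type_a)
    fb = posterior.frame_for(type_b)
    if len(fa) == 0 or len(fb) == 0:
        raise ValueError(f"posterior lacks entries for {type_a!r} or {type_b!r}")
    common = fa.index.intersection(fb.index)
    gap = fa.loc[common, "ci_low"] - fb.loc[common, "ci_high"]
    out = pd.DataFrame({"gene": common, "gap": gap.to_numpy()})
    out = out[out["gap"] > min_gap]
    out = out.sort_values(["gap", "gene"], ascending=[False, True], kind="stable")
    return out.reset_index(drop=True)


def select_markers(
    posterior: PosteriorSummary,
    hierarchy: CellHierarchy,
    cfg: MarkerConfig | None = None,
) -> MarkerList:
    """Top-k positive-separation genes for every ordered sibling pair.

    Internal-node comparisons require the posterior to contain entries for
    internal nodes (fit with ``nodes="all"``), where the node's posterior
    is fitted on the pooled replicates of its leaves.
    """
    cfg = cfg or MarkerConfig()
    cfg.validate()
    have = set(posterior.cell_types)
    records = []
    for level, k in sorted(cfg.k_per_level.items()):
        for group in hierarchy.sibling_groups(level):
            present = [n for n in group if n in have]
            for a in present:
                for b in present:
                    if a == b:
                        continue
                    ranked = pairwise_rank(posterior, a, b, min_gap=cfg.min_gap)
                    for _, row in ranked.head(k).iterrows():
                        records.append((row["gene"], level, a, b, row["gap"]))
    prov = pd.DataFrame(records, columns=PROVENANCE_COLUMNS)
    return MarkerList(provenance=prov)


def build_signature_matrix(
    posterior: PosteriorSummary,
    markers: MarkerList,
    hierarchy: CellHierarchy,
) -> pd.DataFrame:
    """Marker-gene x leaf-cell-type matrix of posterior mean abundances.

    Rows are the marker genes (sorted), columns follow hierarchy leaf
    order; values are on the common TMM/CPM scale of the abundance fit.
    """
    genes = markers.genes
    leaves = [t for t in hierarchy.leaves if t in set(posterior.cell_types)]
    mat = posterior.mean_matrix()
    missing = [g for g in genes if g not in mat.index]
    if missing:
        raise ValueError(f"markers absent from posterior: {missing[:5]}")
    sig = mat.loc[genes, leaves]
    sig.index.name = "gene"
    sig.columns.name = "cell_type"
    return sig
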