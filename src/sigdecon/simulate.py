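"""Synthetic reference transcriptomes, clinical tables, and foreign profiles.

The generator emulates the statistical structure of a curated multi-study
reference: per cell type, replicate count profiles are negative-binomial
with cell-type-specific means (planted marker genes elevated by a known
fold change over a shared baseline), edgeR-style mean/dispersion
parameterization (Var = mu + phi * mu^2), and log-uniform library-size
factors. Everything is deterministic under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hierarchy import CellHierarchy

__all__ = [
    "GenerativeSpec",
    "ReferenceSet",
    "generate_reference",
    "generate_clinical",
    "generate_foreign_profile",
]


@dataclass
class GenerativeSpec:
    """Parameters of the synthetic reference generator.

    Defaults reflect a small but realistic curated reference: tens of
    counts expected per gene, 8-fold marker elevation, moderate biological
    overdispersion (phi = 0.1), ten replicates per cell type, and a 4x
    spread of sequencing depths.
    """

    n_genes: int = 400
    n_marker_per_type: int = 10
    baseline_mean: float = 50.0
    fold_change: float = 8.0
    dispersion: float = 0.1
    library_size_range: tuple[float, float] = (0.5, 2.0)
    replicates_per_type: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.fold_change < 1:
            raise ValueError("fold_change must be >= 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.replicates_per_type < 1:
            raise ValueError("replicates_per_type must be >= 1")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ValueError("library_size_range must be an increasing pair of positives")


@dataclass
class ReferenceSet:
    """Gene x replicate raw-count matrix with cell-type labels.

    ``missing`` holds (cell_type, gene) pairs whose observations are to be
    treated as absent when fitting the abundance model — the synthetic
    analogue of a heterogeneous reference where not every gene was
    quantified in every study.
    """

    counts: pd.DataFrame            # genes x replicates, non-negative ints
    replicate_labels: pd.Series     # replicate -> leaf cell type
    hierarchy: CellHierarchy
    planted_markers: dict[str, str] = field(default_factory=dict)  # gene -> type
    missing: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        leaves = set(self.hierarchy.leaves)
        bad = set(self.replicate_labels.unique()) - leaves
        if bad:
            raise ValueError(f"labels not in hierarchy leaves: {sorted(bad)}")
        if list(self.counts.columns) != list(self.replicate_labels.index):
            raise ValueError("counts columns and label index disagree")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")

    def replicates_of(self, cell_type: str) -> list[str]:
        return list(self.replicate_labels.index[self.replicate_labels == cell_type])

    def markers_of(self, cell_type: str) -> list[str]:
        return [g for g, t in self.planted_markers.items() if t == cell_type]

    def to_tsv(self, counts_path, labels_path) -> None:
        out = self.counts.copy()
        out.insert(0, "gene", out.index)
        out.to_csv(counts_path, sep="\t", index=False)
        self.replicate_labels.rename("cell_type").rename_axis("replicate").to_csv(
            labels_path, sep="\t"
        )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB draws with Var = mu + phi mu^2 (size r = 1/phi)."""
    r = 1.0 / phi
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def generate_reference(
    spec: GenerativeSpec,
    hierarchy: CellHierarchy,
    missing_fraction: float = 0.0,
) -> ReferenceSet:
    """Draw a planted-marker synthetic reference.

    For each leaf, ``n_marker_per_type`` disjoint genes get NB mean
    ``baseline_mean * fold_change`` in that leaf and ``baseline_mean``
    everywhere else; all remaining genes are baseline in every type.
    ``missing_fraction`` of (type, gene) cells are flagged missing (the
    counts stay in the matrix but carry a missing flag for the fitter).
    """
    spec.validate()
    leaves = hierarchy.leaves
    if len(leaves) < 2:
        raise ValueError("hierarchy must have at least 2 leaves")
    if spec.n_genes < len(leaves) * spec.n_marker_per_type:
        raise ValueError(
            f"n_genes={spec.n_genes} too small for "
            f"{len(leaves)} leaves x {spec.n_marker_per_type} markers"
        )
    rng = np.random.default_rng(spec.seed)
    width = max(4, len(str(spec.n_genes)))
    genes = [f"g{i:0{width}d}" for i in range(1, spec.n_genes + 1)]

    planted: dict[str, str] = {}
    if spec.fold_change > 1:
        for i, leaf in enumerate(leaves):
            block = genes[i * spec.n_marker_per_type : (i + 1) * spec.n_marker_per_type]
            planted.update({g: leaf for g in block})

    lo, hi = spec.library_size_range
    cols, labels = [], []
    blocks = []
    for leaf in leaves:
        mu = np.full(spec.n_genes, spec.baseline_mean)
        for g, t in planted.items():
            if t == leaf:
                mu[genes.index(g)] *= spec.fold_change
        lib = np.exp(rng.uniform(np.log(lo), np.log(hi), size=spec.replicates_per_type))
        block = _nb_draw(rng, mu[:, None] * lib[None, :], spec.dispersion)
        blocks.append(block)
        cols.extend(f"{leaf}_r{j + 1}" for j in range(spec.replicates_per_type))
        labels.extend([leaf] * spec.replicates_per_type)

    counts = pd.DataFrame(np.hstack(blocks), index=genes, columns=cols)
    counts.index.name = "gene"
    missing: set[tuple[str, str]] = set()
    if missing_fraction > 0:
        n_cells = len(leaves) * spec.n_genes
        k = int(round(missing_fraction * n_cells))
        flat = rng.choice(n_cells, size=k, replace=False)
        for idx in flat:
            missing.add((leaves[idx // spec.n_genes], genes[idx % spec.n_genes]))
    return ReferenceSet(
        counts=counts,
        replicate_labels=pd.Series(labels, index=cols, name="cell_type"),
        hierarchy=hierarchy,
        planted_markers=planted,
        missing=missing,
    )


def generate_clinical(
    n: int,
    event_rate: float = 0.5,
    scale: float = 1000.0,
    seed: int = 0,
    distribution: str = "exponential",
    shape: float = 1.5,
) -> pd.DataFrame:
    """Synthetic progression-free-survival table.

    Times (days) are exponential by default (``distribution='weibull'``
    gives Weibull with the given shape and the same scale); events are
    Bernoulli(``event_rate``). Columns: sample_id, time, event.
    """
    if n <= 0:
        raise ValueError("n must be positive (empty clinical table requested)")
    if not 0 < event_rate <= 1:
        raise ValueError("event_rate must be in (0, 1]")
    rng = np.random.default_rng(seed)
    if distribution == "exponential":
        times = rng.exponential(scale, size=n)
    elif distribution == "weibull":
        times = scale * rng.weibull(shape, size=n)
    else:
        raise ValueError(f"unknown distribution {distribution!r}")
    events = rng.binomial(1, event_rate, size=n)
    return pd.DataFrame(
        {
            "sample_id": [f"S{i:04d}" for i in range(1, n + 1)],
            "time": times,
            "event": events,
        }
    )


def generate_foreign_profile(
    spec: GenerativeSpec,
    hierarchy: CellHierarchy,
    name: str = "foreign",
    seed: int | None = None,
) -> pd.Series:
    """NB count profile of a cell type absent from the hierarchy.

    Its planted markers are drawn from genes that are background in every
    leaf, so the foreign signal never overlaps the reference signatures.
    Used to contaminate benchmark mixtures with out-of-signature cells.
    """
    spec.validate()
    if name in hierarchy.leaves:
        raise ValueError(f"foreign type {name!r} collides with a hierarchy leaf")
    rng = np.random.default_rng(spec.seed + 104729 if seed is None else seed)
    width = max(4, len(str(spec.n_genes)))
    genes = [f"g{i:0{width}d}" for i in range(1, spec.n_genes + 1)]
    n_leaf_markers = len(hierarchy.leaves) * spec.n_marker_per_type
    free = genes[n_leaf_markers:]
    if len(free) < spec.n_marker_per_type:
        raise ValueError("not enough background genes for a foreign marker set")
    own = rng.choice(len(free), size=spec.n_marker_per_type, replace=False)
    mu = np.full(spec.n_genes, spec.baseline_mean)
    for j in own:
        mu[genes.index(free[j])] *= spec.fold_change
    counts = _nb_draw(rng, mu, spec.dispersion)
    return pd.Series(counts, index=genes, name=name)
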