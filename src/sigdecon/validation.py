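"""Signature sanity checks: marker-restricted PCA of reference replicates.

If the selected markers carry cell-type identity, reference replicates
restricted to marker genes should segregate by cell type in a principal-
component embedding. The separation is quantified by the mean silhouette
coefficient of the type labels in PC space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .markers import MarkerList
from .normalize import scale_counts
from .simulate import ReferenceSet

__all__ = ["Embedding", "pca_markers", "separation_score"]


@dataclass
class Embedding:
    coordinates: pd.DataFrame        # replicates x components
    explained_variance: np.ndarray   # variance per component
    explained_variance_ratio: np.ndarray
    labels: pd.Series                # replicate -> cell type


def pca_markers(
    ref: ReferenceSet,
    markers: MarkerList | list[str] | None,
    scope: str = "root",
    n_components: int = 2,
) -> Embedding:
    """PCA of reference replicates on marker genes within a hierarchy scope.

    ``scope`` is a hierarchy node name; only replicates of its leaf
    descendants enter. ``markers=None`` uses all genes (the baseline the
    marker-restricted embedding is compared against). Counts are
    TMM/CPM-scaled, log1p-transformed and gene-centered; components are
    sign-fixed so the largest-magnitude loading is positive.
    """
    node = ref.hierarchy.root if scope in ("root", "all-types") else scope
    scope_leaves = set(ref.hierarchy.leaf_descendants(node))
    keep = ref.replicate_labels.index[ref.replicate_labels.isin(scope_leaves)]
    if len(keep) < 3:
        raise ValueError(f"scope {scope!r} has fewer than 3 replicates")
    genes = None if markers is None else (
        markers.genes if isinstance(markers, MarkerList) else list(markers)
    )
    X = scale_counts(ref.counts)[keep]
    if genes is not None:
        if len(genes) < 2:
            raise ValueError("need at least 2 marker genes in scope")
        X = X.loc[genes]
    M = np.log1p(X.to_numpy(dtype=float)).T  # replicates x genes
    M = M - M.mean(axis=0, keepdims=True)
    d = min(n_components, len(keep) - 1, M.shape[1])
    pca = PCA(n_components=d, svd_solver="full")
    coords = pca.fit_transform(M)
    for k in range(d):  # deterministic component orientation
        j = int(np.argmax(np.abs(pca.components_[k])))
        if pca.components_[k, j] < 0:
            coords[:, k] *= -1.0
    return Embedding(
        coordinates=pd.DataFrame(
            coords, index=keep, columns=[f"PC{i + 1}" for i in range(d)]
        ),
        explained_variance=pca.explained_variance_.copy(),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        labels=ref.replicate_labels.loc[keep],
    )


def separation_score(emb: Embedding, labels: pd.Series | None = None) -> float:
    """Mean silhouette coefficient of label classes in the embedding.

    Classes with a single member are excluded (with a warning) since the
    silhouette is undefined for them.
    """
    labels = emb.labels if labels is None else labels.loc[emb.coordinates.index]
    counts = labels.value_counts()
    singletons = counts.index[counts == 1]
    if len(singletons):
        warnings.warn(
            f"excluding singleton classes from silhouette: {list(singletons)}",
            stacklevel=2,
        )
        keep = labels.index[~labels.isin(singletons)]
        labels = labels.loc[keep]
    else:
        keep = labels.index
    if labels.nunique() < 2:
        raise ValueError("separation score needs >= 2 label classes")
    X = emb.coordinates.loc[keep].to_numpy()
    return float(silhouette_score(X, labels.to_numpy()))
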