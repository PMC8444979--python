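"""Shared paths and loaders for the analysis drivers."""

from pathlib import Path

import pandas as pd

from sigdecon.hierarchy import CellHierarchy
from sigdecon.simulate import ReferenceSet

BASE = Path(__file__).resolve().parents[1] / "results"
SEED = 7


def load_reference() -> ReferenceSet:
    data = BASE / "data"
    counts = pd.read_csv(data / "reference_counts.tsv", sep="\t", index_col="gene")
    labels = pd.read_csv(
        data / "reference_labels.tsv", sep="\t", index_col="replicate"
    )["cell_type"]
    hierarchy = CellHierarchy.from_yaml(data / "hierarchy.yaml")
    return ReferenceSet(counts=counts, replicate_labels=labels, hierarchy=hierarchy)


def load_signature() -> pd.DataFrame:
    return pd.read_csv(BASE / "signature.tsv", sep="\t", index_col="gene")


def load_clinical_pool() -> pd.DataFrame:
    return pd.read_csv(BASE / "data" / "clinical_pool.tsv", sep="\t")
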