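"""Power surface of the survival-association benchmark.

Runs the full benchmark (Dirichlet proportions coupled to survival,
mixture composition, deconvolution, censoring, multiple Cox, pooled ROC)
over a small grid of slope S and foreign-cell proportion P at N = 250,
63 runs per condition with paired seeds, and writes the AUC table.
This is the long-running driver (~10 minutes).
"""

import pandas as pd

import sigdecon as sd
from _common import BASE, SEED, load_clinical_pool, load_reference, load_signature

GRID = [
    (250, 1.0, 0.0),
    (250, 0.6, 0.0),
    (250, 0.2, 0.0),
    (250, 0.0, 0.0),
    (250, 1.0, 0.4),
    (250, 1.0, 0.8),
]


def main() -> None:
    ref = load_reference()
    signature = load_signature()
    pool = load_clinical_pool()
    foreign_counts = pd.read_csv(
        BASE / "data" / "foreign_profile.tsv", sep="\t", index_col="gene"
    ).iloc[:, 0]

    base_cfg = sd.SimulationConfig(runs_per_condition=63, seed=SEED)
    table = sd.run_grid(
        base_cfg, GRID, ref, signature, pool, foreign_profile=foreign_counts
    )
    table.to_csv(BASE / "benchmark_auc.tsv", sep="\t", index=False)

    print("pooled AUC per condition (63 runs each):")
    print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    by = {(s, p): a for _, s, p, a in table[["S", "P", "auc"]].itertuples()}
    print(f"detection is far above chance at S=1 (AUC {by[(1.0, 0.0)]:.2f}) and "
          f"at chance without a planted slope (AUC {by[(0.0, 0.0)]:.2f}); "
          "orderings between adjacent conditions can fluctuate within "
          "Monte-Carlo error at 63 runs.")
    print(f"wrote {BASE}/benchmark_auc.tsv")


if __name__ == "__main__":
    main()
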