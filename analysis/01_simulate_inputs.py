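"""Generate the synthetic study inputs.

Writes the planted-marker reference (counts + labels + hierarchy), the
synthetic clinical pool, and the foreign (out-of-signature) profile used
for contamination experiments. Everything downstream starts from these
files.
"""

from pathlib import Path

import sigdecon as sd

OUT = Path(__file__).resolve().parents[1] / "results" / "data"
SEED = 7


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    hierarchy = sd.load_default_hierarchy()
    spec = sd.GenerativeSpec(seed=SEED)
    ref = sd.generate_reference(spec, hierarchy)
    ref.to_tsv(OUT / "reference_counts.tsv", OUT / "reference_labels.tsv")
    hierarchy.to_yaml(OUT / "hierarchy.yaml")

    clinical = sd.generate_clinical(400, event_rate=0.7, scale=1000.0, seed=SEED + 4)
    clinical.to_csv(OUT / "clinical_pool.tsv", sep="\t", index=False)

    foreign = sd.generate_foreign_profile(spec, hierarchy)
    foreign.rename_axis("gene").to_csv(OUT / "foreign_profile.tsv", sep="\t")

    n_types = len(hierarchy.leaves)
    print(f"reference: {ref.counts.shape[0]} genes x {ref.counts.shape[1]} replicates, "
          f"{n_types} cell types, {len(ref.planted_markers)} planted markers")
    print(f"clinical pool: {len(clinical)} samples, "
          f"{int(clinical['event'].sum())} events, "
          f"median time {clinical['time'].median():.0f} days")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
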