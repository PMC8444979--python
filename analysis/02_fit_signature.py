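"""Fit the NB abundance model and derive the marker signature.

Reads the reference written by 01_simulate_inputs.py, fits posterior
abundance for every hierarchy node (leaves and pooled internal nodes),
selects markers by credible-interval separation (top 5/10/20 per ordered
pair at levels 1/2/3), and writes the posterior table, the marker
provenance, and the signature matrix.
"""

import sigdecon as sd
from _common import BASE, load_reference


def main() -> None:
    ref = load_reference()
    posterior = sd.fit_abundance_model(ref, nodes="all")
    posterior.to_tsv(BASE / "posterior.tsv")

    marker_list = sd.select_markers(posterior, ref.hierarchy)
    marker_list.to_tsv(BASE / "markers.tsv")
    signature = sd.build_signature_matrix(posterior, marker_list, ref.hierarchy)
    signature.to_csv(BASE / "signature.tsv", sep="\t")

    n_pairs = len(posterior.table)
    per_level = marker_list.provenance.groupby("level")["gene"].nunique()
    print(f"posterior: {n_pairs} (node, gene) summaries "
          f"over {len(posterior.cell_types)} nodes")
    print(f"markers: {len(marker_list.genes)} unique genes "
          f"(per level: {per_level.to_dict()})")
    print(f"signature: {signature.shape[0]} genes x {signature.shape[1]} cell types")
    print(f"wrote {BASE}/posterior.tsv, markers.tsv, signature.tsv")


if __name__ == "__main__":
    main()
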