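"""TF binding presence across cell types and stage-preference clustering.

Reads the FIMO-style TFBS table (strict p < 1e-5 filter, motifs
collapsed per TF), counts bound enhancers per TF per cell type, row-
normalizes into the weighted presence matrix, clusters TFs into three
stage-preference groups with k-means, and groups TFs by their peak
expression cell type.  Tables under results/tf_presence/.
"""

import importlib

import pandas as pd
from common import RESULTS, STUDY_CONFIG, SYNTH_DIR

from epinet.io_formats import read_fimo_tsv, read_tpm_table
from epinet.tf_presence import (
    binary_presence_matrix,
    cluster_tf_profiles,
    group_tfs_by_expression,
    weighted_presence_matrix,
)

build = importlib.import_module("03_build_networks")

OUT = RESULTS / "tf_presence"


def main() -> None:
    cfg, nets = build.load_networks()
    OUT.mkdir(parents=True, exist_ok=True)

    tfbs = read_fimo_tsv(SYNTH_DIR / "fimo.tsv", p_threshold=1e-5)
    print(f"TFBS rows after p < 1e-5 filter and motif collapsing: {len(tfbs)} "
          f"({tfbs['tf'].nunique()} TFs)")

    counts = binary_presence_matrix(tfbs, nets)
    weights = weighted_presence_matrix(counts)
    counts.to_csv(OUT / "presence_counts.tsv", sep="\t")
    weights.to_csv(OUT / "presence_weights.tsv", sep="\t")

    clusters = cluster_tf_profiles(weights, cfg.stage_map, seed=cfg.seed)
    assign = pd.Series(clusters.assignment, name="cluster")
    assign.rename_axis("tf").to_csv(OUT / "tf_clusters.tsv", sep="\t")
    print("\nweighted-presence k-means clusters (k=3):")
    print(assign.value_counts().to_string())

    tpm_tables = {ct: read_tpm_table(SYNTH_DIR / f"tpm_{ct}.tsv") for ct in cfg.cell_types}
    grouping = group_tfs_by_expression(tpm_tables, list(weights.index), cfg.stage_map)
    grouping.to_csv(OUT / "tf_expression_groups.tsv", sep="\t")
    print("\nTFs grouped by peak-expression stage:")
    print(grouping["stage"].value_counts(dropna=False).to_string())


if __name__ == "__main__":
    main()
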