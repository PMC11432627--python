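"""Build the collapsed and subset networks and classify sub-structures.

Reads the per-cell-type EPI tables written by 01_simulate.py, applies
the prediction filters, concatenates the six networks (collapsed
network, duplicates kept, enhancers merged at >= 1 bp overlap), builds
the nine-category subset network (100-bp enhancer clustering), and
labels every EPI C1-C4.  Tables under results/networks/.
"""

import pandas as pd
from common import RESULTS, STUDY_CONFIG, SYNTH_DIR

from epinet.abc_scoring import filter_epis
from epinet.io_formats import read_epi_table
from epinet.network_builder import (
    EPINetwork,
    build_collapsed_network,
    build_subset_network,
    classify_substructure,
    subset_substructures,
    substructure_distribution,
)

OUT = RESULTS / "networks"


def load_networks():
    cfg = STUDY_CONFIG
    nets = []
    for ct in cfg.cell_types:
        table = filter_epis(read_epi_table(SYNTH_DIR / f"epi_{ct}.tsv"))
        nets.append(EPINetwork(table, ct))
    return cfg, nets


def main() -> None:
    cfg, nets = load_networks()
    OUT.mkdir(parents=True, exist_ok=True)

    collapsed, merged_enh = build_collapsed_network(nets)
    merged_enh.to_csv(OUT / "merged_enhancers.bed", sep="\t", header=False, index=False)
    print(f"collapsed network: {len(collapsed)} EPIs, "
          f"{collapsed[['chrom', 'start', 'end']].drop_duplicates().shape[0]} unique enhancers "
          f"({len(merged_enh)} after overlap-merging), "
          f"{collapsed['target_gene'].nunique()} unique promoters")

    dists = {}
    for net in nets:
        dists[net.cell_type] = substructure_distribution(classify_substructure(net))
    dist_table = pd.DataFrame(dists).T
    dist_table.to_csv(OUT / "substructure_collapsed.tsv", sep="\t")
    print("\nper-cell-type sub-structure fractions (collapsed):")
    print(dist_table.round(3).to_string())

    subset = build_subset_network(nets, list(cfg.cell_types), cfg.stage_map)
    subset["substructure"] = subset_substructures(subset)
    subset.to_csv(OUT / "subset_network.tsv", sep="\t", index=False)
    cat_counts = subset["category"].value_counts()
    print(f"\nsubset network: {len(subset)} merged EPIs")
    print(cat_counts.to_string())
    analysed = subset[subset["category"] != "Removed"]
    sub_dist = substructure_distribution(analysed["substructure"])
    sub_dist.to_frame("fraction").to_csv(OUT / "substructure_subset.tsv", sep="\t")
    coll_dist = substructure_distribution(
        pd.concat([classify_substructure(n) for n in nets], ignore_index=True)
    )
    shift = (sub_dist - coll_dist).round(3)
    print("\nsub-structure fractions, subset vs collapsed (C1..C4):")
    print(pd.DataFrame({"subset": sub_dist, "collapsed": coll_dist, "shift": shift}).round(3).to_string())
    print(f"\nC1+C2 share: subset {sub_dist['C1'] + sub_dist['C2']:.3f} "
          f"vs collapsed {coll_dist['C1'] + coll_dist['C2']:.3f}")


if __name__ == "__main__":
    main()
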