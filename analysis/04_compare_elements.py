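"""Cross-cell-type element comparison: uniqueness and Jaccard matrices.

Quantifies how much of each cell type's regulatory repertoire is its
own: the fraction of enhancers with no >= 1-bp overlap in any other
cell type (planted at 35%), the fraction of promoters whose gene symbol
is private, and the pairwise Jaccard similarity for both element kinds.
Tables under results/element_comparison/.
"""

import importlib

import pandas as pd
from common import RESULTS

from epinet.element_comparison import (
    jaccard_long_format,
    jaccard_matrix,
    unique_element_fraction,
)

build = importlib.import_module("03_build_networks")

OUT = RESULTS / "element_comparison"


def main() -> None:
    _, nets = build.load_networks()
    OUT.mkdir(parents=True, exist_ok=True)

    uniq = pd.DataFrame(
        {
            kind: unique_element_fraction(nets, kind)
            for kind in ("enhancer", "promoter")
        }
    )
    uniq.to_csv(OUT / "uniqueness.tsv", sep="\t")
    print("fraction of elements unique to each cell type:")
    print(uniq.round(3).to_string())
    print(f"\nmean unique enhancers: {uniq['enhancer'].mean():.1%} "
          f"(vs 35% planted before filtering); promoters: {uniq['promoter'].mean():.1%}")

    tidy = []
    for kind in ("enhancer", "promoter"):
        matrix = jaccard_matrix(nets, kind)
        matrix.values.to_csv(OUT / f"jaccard_{kind}.tsv", sep="\t")
        tidy.append(jaccard_long_format(matrix))
    pd.concat(tidy, ignore_index=True).to_csv(OUT / "jaccard_long.tsv", sep="\t", index=False)

    enh = pd.read_csv(OUT / "jaccard_enhancer.tsv", sep="\t", index_col=0)
    within = (enh.loc["ESC", "NSC"] + enh.loc["NSC", "NPC"] + enh.loc["AD", "Ngn2"]) / 3
    across = (enh.loc["ESC", "AD"] + enh.loc["NSC", "Motor"] + enh.loc["NPC", "Ngn2"]) / 3
    print(f"\nenhancer Jaccard within stages {within:.3f} vs across stages {across:.3f}")


if __name__ == "__main__":
    main()
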