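"""Cross-cell-type comparison of regulatory elements.

Enhancers are compared as intervals under the >= 1-bp overlap rule;
promoters are compared as exact gene symbols.  Two summaries are
computed per element kind: the fraction of elements unique to each cell
type, and the 6 x 6 Jaccard similarity matrix between cell types.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import covered_bases, merge_intervals, overlaps_any
from .network_builder import ENHANCER_KEY, EPINetwork

ELEMENT_KINDS = ("enhancer", "promoter")


@dataclass
class OverlapMatrix:
    """Symmetric Jaccard matrix between cell types for one element kind."""

    labels: list[str]
    values: pd.DataFrame
    element_kind: str


def overlap_elements(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Elements of ``a`` that overlap >= 1 bp with any element of ``b``."""
    return a[overlaps_any(a, b)]


def unique_element_fraction(
    networks: list[EPINetwork], kind: str = "enhancer"
) -> pd.Series:
    """Per-cell-type fraction of elements found in no other cell type.

    An enhancer is unique when it has zero >= 1-bp overlaps with all five
    other cell types' enhancer sets (evaluated on the original per-cell-
    type intervals, pre-merge); a promoter is unique when its gene symbol
    appears in no other cell type's network.
    """
    if kind not in ELEMENT_KINDS:
        raise ValueError(f"kind must be one of {ELEMENT_KINDS}")
    fractions = {}
    if kind == "enhancer":
        enh = [n.enhancers() for n in networks]
        for i, net in enumerate(networks):
            others = pd.concat([e for j, e in enumerate(enh) if j != i], ignore_index=True)
            shared = overlaps_any(enh[i], others)
            fractions[net.cell_type] = float((~shared).mean()) if len(enh[i]) else np.nan
    else:
        gene_sets = [n.genes() for n in networks]
        for i, net in enumerate(networks):
            others = set().union(*(g for j, g in enumerate(gene_sets) if j != i))
            mine = gene_sets[i]
            fractions[net.cell_type] = (
                len(mine - others) / len(mine) if mine else np.nan
            )
    return pd.Series(fractions, name=f"unique_{kind}_fraction")


def _interval_jaccard(a: pd.DataFrame, b: pd.DataFrame, mode: str) -> float:
    if len(a) == 0 and len(b) == 0:
        return np.nan
    if mode == "basepair":
        inter = covered_bases(a) + covered_bases(b) - covered_bases(
            pd.concat([a, b], ignore_index=True)
        )
        union = covered_bases(pd.concat([a, b], ignore_index=True))
        return inter / union if union else np.nan
    # element mode: merge the union into >=1-bp overlap clusters, then count
    # clusters containing elements of a, of b, and of both
    union_df = pd.concat([a[ENHANCER_KEY], b[ENHANCER_KEY]], ignore_index=True)
    merged, cluster = merge_intervals(union_df, require_overlap=True)
    from_a = np.zeros(len(merged), dtype=bool)
    from_b = np.zeros(len(merged), dtype=bool)
    from_a[np.unique(cluster[: len(a)])] = True
    from_b[np.unique(cluster[len(a):])] = True
    n_a = int(from_a.sum())
    n_b = int(from_b.sum())
    n_both = int((from_a & from_b).sum())
    denom = n_a + n_b - n_both
    return n_both / denom if denom else np.nan


def jaccard_matrix(
    networks: list[EPINetwork], kind: str = "enhancer", mode: str = "element"
) -> OverlapMatrix:
    """Pairwise Jaccard similarity between cell types.

    For enhancers the default ``element`` mode merges the two interval
    sets into union clusters U and computes J = |both| / (|a| + |b| -
    |both|) over clusters; ``basepair`` mode computes shared bp / union
    bp instead.  For promoters a plain set Jaccard on gene symbols is
    used.  Pairs of empty sets are reported as NaN.
    """
    if kind not in ELEMENT_KINDS:
        raise ValueError(f"kind must be one of {ELEMENT_KINDS}")
    if mode not in ("element", "basepair"):
        raise ValueError("mode must be 'element' or 'basepair'")
    if len(networks) < 2:
        raise ValueError("need at least two networks")
    labels = [n.cell_type for n in networks]
    k = len(networks)
    vals = np.eye(k)
    if kind == "enhancer":
        sets = [n.enhancers() for n in networks]
        for i in range(k):
            vals[i, i] = 1.0 if len(sets[i]) else np.nan
            for j in range(i + 1, k):
                vals[i, j] = vals[j, i] = _interval_jaccard(sets[i], sets[j], mode)
    else:
        sets = [n.genes() for n in networks]
        for i in range(k):
            vals[i, i] = 1.0 if sets[i] else np.nan
            for j in range(i + 1, k):
                union = sets[i] | sets[j]
                vals[i, j] = vals[j, i] = (
                    len(sets[i] & sets[j]) / len(union) if union else np.nan
                )
    frame = pd.DataFrame(vals, index=labels, columns=labels)
    return OverlapMatrix(labels=labels, values=frame, element_kind=kind)


def jaccard_long_format(matrix: OverlapMatrix) -> pd.DataFrame:
    """Tidy (cell_a, cell_b, kind, jaccard) rows for the upper triangle."""
    rows = []
    labels = matrix.labels
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            rows.append((a, labels[j], matrix.element_kind, matrix.values.iloc[i, j]))
    return pd.DataFrame(rows, columns=["cell_a", "cell_b", "kind", "jaccard"])


def plot_jaccard_heatmap(matrix: OverlapMatrix, path) -> None:
    """Minimal heatmap rendering of a Jaccard matrix to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(matrix.values.to_numpy(), vmin=0, vmax=1, cmap="Reds")
    ax.set_xticks(range(len(matrix.labels)), matrix.labels, rotation=45)
    ax.set_yticks(range(len(matrix.labels)), matrix.labels)
    ax.set_title(f"{matrix.element_kind} Jaccard")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
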