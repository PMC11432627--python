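"""EPI network construction and classification.

Three constructions are provided:

* the *collapsed network*: the six per-cell-type EPI tables concatenated
  with duplicates kept, alongside a separately maintained list of
  enhancers merged wherever they overlap by >= 1 bp;
* the *subset network*: EPIs whose enhancers lie within 100 bp of each
  other are clustered, each cluster x target-gene pair collects a
  6-vector of per-cell-type ABC scores, and the vector is classified
  into one of nine categories (six cell-type-specific, Progenitor,
  Mature, ubiquitous) or removed when it mixes stages;
* the *sub-structure labels* C1-C4: each EPI is classified by whether
  its enhancer regulates one or several promoters and its promoter is
  regulated by one or several enhancers, within a single network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import merge_intervals
from .io_formats import EPI_COLUMNS

SUBSTRUCTURES = ("C1", "C2", "C3", "C4")

ENHANCER_KEY = ["chrom", "start", "end"]

SUBSET_MERGE_GAP = 100


@dataclass
class EPINetwork:
    """A set of EPI records within one cell type, with degree indices.

    Promoter identity is the target-gene symbol; enhancer identity is
    the exact (chrom, start, end) triple.
    """

    records: pd.DataFrame
    cell_type: str | None = None

    def __post_init__(self) -> None:
        missing = [c for c in EPI_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"EPI frame missing column(s): {missing}")
        self.records = self.records.reset_index(drop=True)
        if self.cell_type is None:
            cts = self.records["cell_type"].unique()
            self.cell_type = cts[0] if len(cts) == 1 else None

    def __len__(self) -> int:
        return len(self.records)

    @property
    def enhancer_key(self) -> pd.Series:
        r = self.records
        return r["chrom"].str.cat([r["start"].astype(str), r["end"].astype(str)], sep=":")

    @property
    def enhancer_degree(self) -> pd.Series:
        """Distinct target genes per enhancer."""
        return self.records.groupby(self.enhancer_key)["target_gene"].nunique()

    @property
    def promoter_degree(self) -> pd.Series:
        """Distinct enhancers per target gene."""
        return self.records.assign(_e=self.enhancer_key).groupby("target_gene")[
            "_e"
        ].nunique()

    def enhancers(self) -> pd.DataFrame:
        """Distinct enhancer intervals of the network."""
        return self.records[ENHANCER_KEY].drop_duplicates().reset_index(drop=True)

    def genes(self) -> set[str]:
        return set(self.records["target_gene"])


def build_collapsed_network(
    networks: list[EPINetwork],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Concatenate per-cell-type networks; merge their enhancer regions.

    Returns ``(collapsed_records, merged_enhancers)``: the record
    concatenation keeps cross-cell-type duplicates (each row retains its
    cell-type label); the merged enhancer list collapses any >= 1-bp
    overlapping enhancer regions to their union interval.
    """
    collapsed = pd.concat([n.records for n in networks], ignore_index=True)
    all_enh = collapsed[ENHANCER_KEY].drop_duplicates().reset_index(drop=True)
    merged, _ = merge_intervals(all_enh, require_overlap=True)
    return collapsed, merged.drop(columns="n_members")


def merge_within_gap(
    enhancers: pd.DataFrame, gap: int = SUBSET_MERGE_GAP
) -> tuple[pd.DataFrame, np.ndarray]:
    """Cluster enhancer regions lying within ``gap`` bp of each other.

    Clustering is transitive; each cluster's interval is the union span.
    Returns the cluster table and a membership array mapping each input
    row to its cluster index.
    """
    return merge_intervals(enhancers, gap=gap, require_overlap=False)


def assign_subset_category(
    score_vector, cell_types, stage_map
) -> str:
    """Nine-category assignment of a merged EPI's per-cell-type scores.

    Decision order (the ubiquitous rule must precede the mixed-stage
    removal because >= 5 of 6 cell types necessarily spans both stages):

    1. non-zero in >= 5 of the 6 cell types -> ``"Ubi"``;
    2. non-zero in exactly one cell type -> that cell type's label;
    3. non-zero in >= 2 cell types, all progenitor -> ``"Progenitor"``;
    4. non-zero in >= 2 cell types, all mature -> ``"Mature"``;
    5. otherwise (2-4 cell types mixing stages) -> ``"Removed"``.
    """
    v = np.asarray(score_vector, dtype=float)
    if v.shape != (6,):
        raise ValueError(f"score vector must have length 6, got {v.shape}")
    nonzero = np.flatnonzero(v > 0)
    if len(nonzero) == 0:
        raise ValueError("score vector is all zero")
    if len(nonzero) >= 5:
        return "Ubi"
    if len(nonzero) == 1:
        return cell_types[nonzero[0]]
    stages = {stage_map[cell_types[i]] for i in nonzero}
    if stages == {"progenitor"}:
        return "Progenitor"
    if stages == {"mature"}:
        return "Mature"
    return "Removed"


def build_subset_network(
    networks: list[EPINetwork],
    cell_types: list[str],
    stage_map: dict[str, str],
    gap: int = SUBSET_MERGE_GAP,
    score_agg: str = "max",
) -> pd.DataFrame:
    """Build the nine-category subset network from filtered cell-type networks.

    Enhancer regions within ``gap`` bp (across all cell types) are
    clustered; each (cluster, target gene) pair is a merged EPI whose
    per-cell-type score is the ``max`` (or ``mean``) ABC score among its
    member records, absent cell types contributing 0.  Returns one row
    per merged EPI with the cluster interval, gene, per-cell-type score
    columns and the assigned ``category``.
    """
    if score_agg not in ("max", "mean"):
        raise ValueError("score_agg must be 'max' or 'mean'")
    records = pd.concat([n.records for n in networks], ignore_index=True)
    clusters, member = merge_within_gap(records[ENHANCER_KEY], gap=gap)
    records = records.assign(cluster=member)
    agg = (
        records.groupby(["cluster", "target_gene", "cell_type"])["abc_score"]
        .agg(score_agg)
        .unstack("cell_type", fill_value=0.0)
        .reindex(columns=list(cell_types), fill_value=0.0)
    )
    score_mat = agg.to_numpy()
    n_nonzero = (score_mat > 0).sum(axis=1)
    labels = np.empty(len(agg), dtype=object)
    prog_mask = np.array([stage_map[ct] == "progenitor" for ct in cell_types])
    nz = score_mat > 0
    any_prog = (nz & prog_mask).any(axis=1)
    any_mat = (nz & ~prog_mask).any(axis=1)
    labels[n_nonzero >= 5] = "Ubi"
    single = n_nonzero == 1
    labels[single] = np.asarray(list(cell_types), dtype=object)[
        np.argmax(nz[single], axis=1)
    ]
    multi = (n_nonzero >= 2) & (n_nonzero < 5)
    labels[multi & any_prog & ~any_mat] = "Progenitor"
    labels[multi & ~any_prog & any_mat] = "Mature"
    labels[multi & any_prog & any_mat] = "Removed"

    idx = agg.index.to_frame(index=False)
    out = pd.DataFrame(
        {
            "chrom": clusters["chrom"].to_numpy()[idx["cluster"]],
            "start": clusters["start"].to_numpy()[idx["cluster"]],
            "end": clusters["end"].to_numpy()[idx["cluster"]],
            "target_gene": idx["target_gene"].to_numpy(),
        }
    )
    for ct in cell_types:
        out[ct] = agg[ct].to_numpy()
    out["category"] = labels
    return out


def classify_substructure(network: EPINetwork) -> pd.Series:
    """Per-EPI sub-structure label within one network.

    For an EPI between enhancer e and gene g, with deg(e) = number of
    distinct genes e regulates and deg(g) = number of distinct enhancers
    regulating g:

    ========  =========  =========
    label     deg(e)     deg(g)
    ========  =========  =========
    C1        1          1
    C2        > 1        1
    C3        1          > 1
    C4        > 1        > 1
    ========  =========  =========
    """
    r = network.records
    ekey = network.enhancer_key
    deg_e = ekey.map(r.groupby(ekey)["target_gene"].nunique())
    deg_p = r["target_gene"].map(
        r.assign(_e=ekey).groupby("target_gene")["_e"].nunique()
    )
    labels = np.where(
        deg_e == 1,
        np.where(deg_p == 1, "C1", "C3"),
        np.where(deg_p == 1, "C2", "C4"),
    )
    return pd.Series(labels, index=r.index, name="substructure")


def subset_substructures(subset: pd.DataFrame) -> pd.Series:
    """Sub-structure labels for a subset network, per category group.

    Each category of the subset network (cell-type-specific, Progenitor,
    Mature, Ubi) is treated as its own EPI set: degrees are computed
    among the merged EPIs sharing that category.  ``Removed`` rows get
    no label (NaN).
    """
    labels = pd.Series(np.nan, index=subset.index, dtype=object, name="substructure")
    for cat, group in subset.groupby("category"):
        if cat == "Removed":
            continue
        from .io_formats import EPI_COLUMNS  # column names only

        pseudo = group.rename(columns={})[["chrom", "start", "end", "target_gene"]]
        pseudo = pseudo.assign(
            cell_type=cat, tss=group["start"], gene_strand="+", abc_score=1.0,
            target_tpm=2.0,
        )
        net = EPINetwork(pseudo[EPI_COLUMNS], cell_type=str(cat))
        labels.loc[group.index] = classify_substructure(net).to_numpy()
    return labels


def substructure_distribution(labels: pd.Series) -> pd.Series:
    """Fraction of EPIs in each sub-structure category (sums to 1)."""
    if len(labels) == 0:
        raise ValueError("empty network: sub-structure distribution undefined")
    frac = labels.value_counts(normalize=True).reindex(SUBSTRUCTURES, fill_value=0.0)
    frac.index.name = "substructure"
    return frac


def substructure_elements(
    networks: list[EPINetwork], element_kind: str = "enhancer", genes: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Pooled (element interval, sub-structure category) pairs.

    Each network is labeled independently; an element inherits the label
    of every EPI it participates in, so one interval may carry several
    categories.  Pairs are deduplicated across networks.  For
    ``element_kind="promoter"`` a stranded gene annotation frame is
    required to derive 2-kb promoter regions.
    """
    frames = []
    for net in networks:
        labels = classify_substructure(net)
        if element_kind == "enhancer":
            df = net.records[ENHANCER_KEY].assign(category=labels.to_numpy())
        elif element_kind == "promoter":
            if genes is None:
                raise ValueError("promoter elements require a gene annotation frame")
            from .variant_enrichment import derive_promoter_regions

            promoters = derive_promoter_regions(genes)
            df = net.records[["target_gene"]].assign(category=labels.to_numpy())
            df = df.merge(promoters, left_on="target_gene", right_on="gene")[
                ENHANCER_KEY + ["category"]
            ]
        else:
            raise ValueError("element_kind must be 'enhancer' or 'promoter'")
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    return out.drop_duplicates().reset_index(drop=True)
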