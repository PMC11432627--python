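"""Transcription-factor presence matrices and stage-preference clustering.

From a collapsed TF-binding table (one row per TF x enhancer after
motif collapsing) and the six cell-type networks, a counts matrix is
built: entry (tf, cell type) = number of that cell type's network
enhancers with at least one predicted site for the TF.  Row-normalizing
the counts gives each TF a weight profile over the six cell types
summing to 1; k-means with k = 3 on the profiles separates TFs with
higher-ranked presence in progenitor cell types, higher-ranked presence
in mature neurons, and approximately equal presence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .network_builder import ENHANCER_KEY, EPINetwork

CLUSTER_LABELS = ("higher_progenitor", "higher_mature", "equal")


@dataclass
class TFClusterResult:
    """k-means stage-preference assignment of TF weight profiles."""

    assignment: dict[str, str]
    k: int
    seed: int
    cluster_of_tf: dict[str, int]
    centers: np.ndarray


def binary_presence_matrix(
    tfbs: pd.DataFrame, networks: list[EPINetwork]
) -> pd.DataFrame:
    """Counts matrix: distinct network enhancers bound per TF per cell type.

    TF-binding rows are joined to network enhancers by exact (chrom,
    start, end); rows referencing an enhancer absent from every network
    are skipped with a warning.  TFs bound nowhere are excluded.
    """
    known = pd.concat([n.enhancers() for n in networks], ignore_index=True)
    known_keys = set(map(tuple, known.itertuples(index=False)))
    tf_keys = list(map(tuple, tfbs[ENHANCER_KEY].itertuples(index=False)))
    unknown = [k not in known_keys for k in tf_keys]
    if any(unknown):
        warnings.warn(
            f"{sum(unknown)} TF-binding rows reference enhancers absent from "
            "all networks; skipped",
            stacklevel=2,
        )
        tfbs = tfbs[~np.array(unknown)]
    counts = {}
    for net in networks:
        joined = net.enhancers().merge(tfbs, on=ENHANCER_KEY)
        counts[net.cell_type] = (
            joined.drop_duplicates(subset=["tf"] + ENHANCER_KEY)
            .groupby("tf")
            .size()
        )
    mat = pd.DataFrame(counts).fillna(0).astype(int)
    mat = mat[[n.cell_type for n in networks]]
    mat = mat[mat.sum(axis=1) > 0].sort_index()
    mat.index.name = "tf"
    return mat


def weighted_presence_matrix(counts: pd.DataFrame) -> pd.DataFrame:
    """Row-normalize a counts matrix so each TF's weights sum to 1.

    TFs with zero total binding are excluded with a warning.
    """
    totals = counts.sum(axis=1)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"excluding {int(zero.sum())} TF(s) with zero total binding",
            stacklevel=2,
        )
        counts = counts[~zero]
        totals = totals[~zero]
    return counts.div(totals, axis=0)


def cluster_tf_profiles(
    weights: pd.DataFrame,
    stage_map: dict[str, str],
    k: int = 3,
    seed: int = 0,
    n_restarts: int = 10,
) -> TFClusterResult:
    """k-means clustering of TF weight profiles into stage-preference groups.

    Clusters (Euclidean k-means, ``n_restarts`` initialisations, best
    inertia) are labeled by the gap between their centre's mean weight
    in progenitor vs mature columns: largest gap -> ``higher_progenitor``,
    smallest -> ``higher_mature``, middle -> ``equal``.  Ties in the gap
    ordering break deterministically by cluster index.
    """
    if len(weights) < k:
        raise ValueError(f"need at least k={k} TFs, got {len(weights)}")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    cluster = km.fit_predict(weights.to_numpy())
    prog_cols = [c for c in weights.columns if stage_map[c] == "progenitor"]
    mat_cols = [c for c in weights.columns if stage_map[c] == "mature"]
    prog_idx = [weights.columns.get_loc(c) for c in prog_cols]
    mat_idx = [weights.columns.get_loc(c) for c in mat_cols]
    delta = km.cluster_centers_[:, prog_idx].mean(axis=1) - km.cluster_centers_[
        :, mat_idx
    ].mean(axis=1)
    order = np.argsort(-delta, kind="stable")  # descending gap, stable ties
    label_of_cluster = {}
    names = list(CLUSTER_LABELS) if k == 3 else [f"cluster{i}" for i in range(k)]
    if k == 3:
        label_of_cluster[order[0]] = "higher_progenitor"
        label_of_cluster[order[2]] = "higher_mature"
        label_of_cluster[order[1]] = "equal"
    else:
        for rank, c in enumerate(order):
            label_of_cluster[c] = names[rank]
    assignment = {
        tf: label_of_cluster[c] for tf, c in zip(weights.index, cluster)
    }
    return TFClusterResult(
        assignment=assignment,
        k=k,
        seed=seed,
        cluster_of_tf=dict(zip(weights.index, (int(c) for c in cluster))),
        centers=km.cluster_centers_,
    )


def group_tfs_by_expression(
    tpm_tables: dict[str, dict[str, float]],
    tfs: list[str],
    stage_map: dict[str, str],
) -> pd.DataFrame:
    """Group each TF by the cell type with its highest gene expression.

    Returns a frame indexed by TF with columns ``cell_type`` (argmax,
    ties broken by the fixed cell-type order with ``tie`` flagged),
    ``stage`` (the argmax cell type's stage) and ``tie``.  TFs absent
    from every TPM table get cell_type/stage = NaN (the unassigned
    report).
    """
    cell_types = list(tpm_tables)
    rows = []
    for tf in tfs:
        values = [tpm_tables[ct].get(tf) for ct in cell_types]
        present = [v for v in values if v is not None]
        if not present:
            rows.append((tf, np.nan, np.nan, False))
            continue
        best = max(present)
        winners = [ct for ct, v in zip(cell_types, values) if v == best]
        rows.append((tf, winners[0], stage_map[winners[0]], len(winners) > 1))
    return pd.DataFrame(
        rows, columns=["tf", "cell_type", "stage", "tie"]
    ).set_index("tf")
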