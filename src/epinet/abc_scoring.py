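"""Simplified Activity-by-Contact (ABC) scoring of enhancer-promoter pairs.

The ABC model scores a candidate enhancer *e* for a promoter *p* as

    ABC(e, p) = A(e) * C(e, p) / sum_j A(j) * C(j, p)

where A is the enhancer's activity (here the geometric mean of its
ATAC-seq and H3K27ac read counts), C is the contact frequency (a
power-law decay of genomic distance standing in for Hi-C), and the sum
runs over all candidate enhancers within 5 Mb of the promoter.  Scores
for one promoter therefore sum to 1 before filtering, and any rescaling
of the contact curve cancels.

Predicted interactions are kept when ABC >= 0.02 and the target gene is
expressed above 1 TPM in the same cell type.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import GenomicInterval
from .io_formats import MAX_EPI_DISTANCE

#: Score threshold below which an interaction is discarded.
DEFAULT_SCORE_MIN = 0.02
#: Target-gene expression must be strictly greater than this (TPM).
DEFAULT_TPM_MIN = 1.0

ENHANCER_WIDTH = 500

_ACTIVITY_MODES = ("geometric", "arithmetic", "product")


@dataclass(frozen=True)
class CandidateEnhancer:
    """A 500-bp accessibility peak with activity read counts."""

    interval: GenomicInterval
    atac_count: float
    h3k27ac_count: float

    def __post_init__(self) -> None:
        if self.interval.width != ENHANCER_WIDTH:
            raise ValueError(
                f"candidate enhancer must be exactly {ENHANCER_WIDTH} bp wide, "
                f"got {self.interval.width}"
            )
        if self.atac_count < 0 or self.h3k27ac_count < 0:
            raise ValueError("read counts must be >= 0")


@dataclass(frozen=True)
class ContactModel:
    """Power-law contact estimate: C(d) = max(d, d_min) ** -gamma.

    ``d_min`` floors the distance so contact stays finite at d = 0;
    contact is positive and non-increasing in distance.
    """

    gamma: float = 1.0
    d_min: int = 5000

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.d_min < 1:
            raise ValueError("d_min must be >= 1")


def enhancer_activity(enhancer: CandidateEnhancer, mode: str = "geometric") -> float:
    """Activity of an enhancer from its ATAC and H3K27ac read counts."""
    if mode not in _ACTIVITY_MODES:
        raise ValueError(f"mode must be one of {_ACTIVITY_MODES}")
    a, h = enhancer.atac_count, enhancer.h3k27ac_count
    if a < 0 or h < 0:
        raise ValueError("read counts must be >= 0")
    if mode == "geometric":
        return math.sqrt(a * h)
    if mode == "arithmetic":
        return (a + h) / 2
    return a * h


def contact_frequency(distance: int, model: ContactModel) -> float:
    """Estimated contact frequency at a genomic distance (bp)."""
    if distance < 0:
        raise ValueError("distance must be >= 0")
    return float(max(distance, model.d_min)) ** -model.gamma


def compute_abc_scores(
    enhancers: list[CandidateEnhancer],
    tss: int,
    model: ContactModel | None = None,
    activity_mode: str = "geometric",
) -> list[tuple[CandidateEnhancer, float]]:
    """ABC scores of candidate enhancers for one promoter.

    Enhancers whose midpoint lies beyond 5 Mb of the TSS are excluded
    from both the numerator set and the normalizing sum; the returned
    scores cover only the in-window enhancers and sum to 1 (or are all 0
    for a degenerate promoter whose enhancers all have zero activity).
    """
    model = model or ContactModel()
    in_window = [
        e for e in enhancers if abs(e.interval.midpoint - tss) <= MAX_EPI_DISTANCE
    ]
    if not in_window:
        raise ValueError("no candidate enhancer within 5 Mb of the TSS")
    weights = np.array(
        [
            enhancer_activity(e, activity_mode)
            * contact_frequency(abs(e.interval.midpoint - tss), model)
            for e in in_window
        ]
    )
    total = weights.sum()
    if total == 0:
        warnings.warn(
            "all enhancer activities are zero for this promoter; scores set to 0",
            stacklevel=2,
        )
        return [(e, 0.0) for e in in_window]
    scores = weights / total
    return list(zip(in_window, scores))


def filter_epis(
    records: pd.DataFrame,
    score_min: float = DEFAULT_SCORE_MIN,
    tpm_min: float = DEFAULT_TPM_MIN,
) -> pd.DataFrame:
    """Apply the EPI prediction filters to an EPI table.

    Keeps rows with ``abc_score >= score_min`` (interactions scored below
    0.02 are removed) and ``target_tpm > tpm_min`` (strictly greater than
    1 TPM).  Row order is preserved.
    """
    keep = (records["abc_score"] >= score_min) & (records["target_tpm"] > tpm_min)
    return records[keep]


def score_epi_tables(
    atac: pd.DataFrame,
    h3k27ac: pd.DataFrame,
    genes: pd.DataFrame,
    tpm: dict[str, float],
    cell_type: str,
    model: ContactModel | None = None,
    activity_mode: str = "geometric",
) -> pd.DataFrame:
    """End-to-end scoring: peak tables -> EPI-dialect table for one cell type.

    ``atac`` and ``h3k27ac`` are BED-like frames (chrom, start, end,
    score=read count) over the *same* 500-bp candidate regions; activity
    pairs them by exact interval.  ``genes`` is a stranded annotation
    frame (chrom, start, end, strand, gene) whose TSS is ``start`` on the
    + strand and ``end`` on the - strand.
    """
    model = model or ContactModel()
    key = ["chrom", "start", "end"]
    merged = atac[key + ["score"]].merge(
        h3k27ac[key + ["score"]], on=key, suffixes=("_atac", "_h3k27ac")
    )
    if merged.empty:
        raise ValueError("no candidate region present in both peak tables")
    if activity_mode == "geometric":
        act = np.sqrt(merged["score_atac"] * merged["score_h3k27ac"])
    elif activity_mode == "arithmetic":
        act = (merged["score_atac"] + merged["score_h3k27ac"]) / 2
    else:
        act = merged["score_atac"] * merged["score_h3k27ac"]
    merged = merged.assign(activity=act, mid=(merged["start"] + merged["end"]) // 2)

    rows = []
    for g in genes.itertuples(index=False):
        tss = g.start if g.strand == "+" else g.end
        cand = merged[merged["chrom"] == g.chrom]
        cand = cand[(cand["mid"] - tss).abs() <= MAX_EPI_DISTANCE]
        if cand.empty:
            continue
        dist = np.maximum((cand["mid"] - tss).abs(), model.d_min).astype(float)
        w = cand["activity"].to_numpy() * dist.to_numpy() ** -model.gamma
        total = w.sum()
        scores = w / total if total > 0 else np.zeros_like(w)
        gene_tpm = float(tpm.get(g.gene, 0.0))
        for (_, r), s in zip(cand.iterrows(), scores):
            rows.append(
                (r["chrom"], r["start"], r["end"], cell_type, g.gene, tss,
                 g.strand, s, gene_tpm)
            )
    from .io_formats import EPI_COLUMNS

    return pd.DataFrame(rows, columns=EPI_COLUMNS)
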