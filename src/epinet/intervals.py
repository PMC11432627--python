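"""Genomic interval primitives.

All coordinates are 0-based half-open (BED convention): an interval
``[start, end)`` covers bases ``start .. end-1``.  Two intervals overlap
iff they share at least one base, i.e. ``a.start < b.end and b.start <
a.end``; intervals that merely touch (``a.end == b.start``) do not.

Interval collections are carried as pandas DataFrames with ``chrom``,
``start`` and ``end`` columns (extra columns pass through untouched);
the operations here are vectorized sweeps over chromosome-sorted arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BED_COLUMNS = ["chrom", "start", "end"]

_VALID_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic region, optionally stranded."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def intervals_to_frame(intervals) -> pd.DataFrame:
    """Pack an iterable of :class:`GenomicInterval` into a BED-like frame."""
    return pd.DataFrame(
        [(iv.chrom, iv.start, iv.end) for iv in intervals], columns=BED_COLUMNS
    )


def _check_frame(df: pd.DataFrame) -> None:
    missing = [c for c in BED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"interval frame missing columns: {missing}")


def merge_intervals(
    df: pd.DataFrame, gap: int = 0, require_overlap: bool = False
) -> tuple[pd.DataFrame, np.ndarray]:
    """Cluster intervals transitively and collapse each cluster to its span.

    With ``require_overlap=True`` only intervals sharing >= 1 bp merge
    (GenomicRanges ``reduce`` on strictly overlapping regions); otherwise
    intervals whose separation is <= ``gap`` bp merge, so ``gap=0`` also
    joins book-ended intervals and ``gap=100`` reproduces the 100-bp
    cluster rule used for the subset network.

    Returns ``(merged, cluster_ids)`` where ``merged`` has one row per
    cluster (chrom, start, end, n_members) sorted by position and
    ``cluster_ids`` maps each *input* row (original order) to its row
    index in ``merged``.
    """
    _check_frame(df)
    if gap < 0:
        raise ValueError("gap must be >= 0")
    n = len(df)
    if n == 0:
        merged = pd.DataFrame(columns=BED_COLUMNS + ["n_members"])
        return merged, np.empty(0, dtype=int)

    order = np.lexsort((df["start"].to_numpy(), df["chrom"].to_numpy()))
    chrom = df["chrom"].to_numpy()[order]
    start = df["start"].to_numpy()[order]
    end = df["end"].to_numpy()[order]

    # running maximum of interval ends within each chromosome block
    new_chrom = np.empty(n, dtype=bool)
    new_chrom[0] = True
    new_chrom[1:] = chrom[1:] != chrom[:-1]

    block_id = np.cumsum(new_chrom) - 1
    cummax_end = _segmented_cummax(end, block_id)

    breaks = np.empty(n, dtype=bool)
    breaks[0] = True
    prev_max = cummax_end[:-1]
    if require_overlap:
        breaks[1:] = new_chrom[1:] | (start[1:] >= prev_max)
    else:
        breaks[1:] = new_chrom[1:] | (start[1:] - prev_max > gap)

    cluster_sorted = np.cumsum(breaks) - 1
    n_clusters = cluster_sorted[-1] + 1

    merged_start = np.full(n_clusters, np.iinfo(np.int64).max, dtype=np.int64)
    merged_end = np.zeros(n_clusters, dtype=np.int64)
    np.minimum.at(merged_start, cluster_sorted, start)
    np.maximum.at(merged_end, cluster_sorted, end)
    first_member = np.searchsorted(cluster_sorted, np.arange(n_clusters))
    counts = np.bincount(cluster_sorted, minlength=n_clusters)

    merged = pd.DataFrame(
        {
            "chrom": chrom[first_member],
            "start": merged_start,
            "end": merged_end,
            "n_members": counts,
        }
    )
    cluster_ids = np.empty(n, dtype=int)
    cluster_ids[order] = cluster_sorted
    return merged, cluster_ids


def _segmented_cummax(values: np.ndarray, segment_id: np.ndarray) -> np.ndarray:
    """Cumulative maximum restarting at each new segment id."""
    out = np.empty_like(values)
    boundaries = np.flatnonzero(np.diff(segment_id, prepend=segment_id[0] - 1))
    for b, e in zip(boundaries, np.append(boundaries[1:], len(values))):
        out[b:e] = np.maximum.accumulate(values[b:e])
    return out


def overlaps_any(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Boolean mask: does each query interval overlap >= 1 bp of subject?

    The subject is coverage-merged first, so the answer depends only on
    the bases the subject set covers.
    """
    _check_frame(query)
    _check_frame(subject)
    result = np.zeros(len(query), dtype=bool)
    if len(query) == 0 or len(subject) == 0:
        return result
    merged, _ = merge_intervals(subject[BED_COLUMNS], gap=0)
    by_chrom = {c: g for c, g in merged.groupby("chrom", sort=False)}
    q_chrom = query["chrom"].to_numpy()
    q_start = query["start"].to_numpy()
    q_end = query["end"].to_numpy()
    for c, sub in by_chrom.items():
        pos = np.flatnonzero(q_chrom == c)
        if pos.size == 0:
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        # candidate = right-most merged interval starting before query end;
        # merged intervals are disjoint, so it is the only one that can hit
        idx = np.searchsorted(starts, q_end[pos], side="left") - 1
        hit = (idx >= 0) & (ends[np.clip(idx, 0, None)] > q_start[pos])
        result[pos] = hit
    return result


def covered_bases(df: pd.DataFrame) -> int:
    """Total number of distinct bases covered by the interval set."""
    if len(df) == 0:
        return 0
    merged, _ = merge_intervals(df[BED_COLUMNS], gap=0, require_overlap=False)
    return int((merged["end"] - merged["start"]).sum())
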