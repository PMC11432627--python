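"""Readers and writers for the external file formats the pipeline touches.

Everything is UTF-8, tab-delimited text; lines starting with ``#`` are
comments.  All readers validate strictly and raise ``FormatError`` with a
line number rather than silently coercing malformed input.

The enhancer-promoter interaction (EPI) table dialect is this package's
own 9-column TSV::

    chrom  start  end  cell_type  target_gene  tss  gene_strand  abc_score  target_tpm

Coordinates are 0-based half-open; ``tss`` is a single base position.
To ingest output of the actual ABC software, map its columns ``chr``,
``start``, ``end``, ``CellType``, ``TargetGene``, ``TargetGeneTSS``,
``ABC.Score`` (plus a strand and TPM lookup from the gene annotation)
onto this dialect.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import GenomicInterval

EPI_COLUMNS = [
    "chrom",
    "start",
    "end",
    "cell_type",
    "target_gene",
    "tss",
    "gene_strand",
    "abc_score",
    "target_tpm",
]

#: Maximum enhancer-midpoint-to-TSS distance for a valid EPI (bp).
MAX_EPI_DISTANCE = 5_000_000

_FIMO_REQUIRED = ["motif_id", "sequence_name", "start", "stop", "strand", "score", "p-value"]

_SEQNAME_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


class FormatError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True)
class EPIRecord:
    """One predicted enhancer-promoter interaction in one cell type."""

    enhancer: GenomicInterval
    cell_type: str
    target_gene: str
    tss: int
    gene_strand: str
    abc_score: float
    target_tpm: float

    def __post_init__(self) -> None:
        if self.abc_score < 0:
            raise ValueError(f"abc_score must be >= 0, got {self.abc_score}")
        if self.target_tpm < 0:
            raise ValueError(f"target_tpm must be >= 0, got {self.target_tpm}")
        if self.gene_strand not in {"+", "-"}:
            raise ValueError(f"gene_strand must be + or -, got {self.gene_strand!r}")
        if abs(self.tss - self.enhancer.midpoint) > MAX_EPI_DISTANCE:
            raise ValueError(
                f"enhancer {self.enhancer} is more than {MAX_EPI_DISTANCE} bp "
                f"from TSS {self.tss}"
            )


def _data_lines(path):
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def read_bed(path) -> pd.DataFrame:
    """Read a BED3/BED4+score file into a frame.

    Columns: chrom, start, end, and (when present) name and score.
    Half-open 0-based semantics are kept as-is.
    """
    rows = []
    n_extra = 0
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
        chrom, s, e = fields[0], fields[1], fields[2]
        try:
            start, end = int(s), int(e)
        except ValueError:
            raise FormatError(
                f"{path}:{lineno}: non-integer coordinates {s!r}, {e!r}"
            ) from None
        if start >= end:
            raise FormatError(f"{path}:{lineno}: start {start} >= end {end}")
        if start < 0:
            raise FormatError(f"{path}:{lineno}: negative start {start}")
        name = fields[3] if len(fields) > 3 else None
        score = None
        if len(fields) > 4:
            try:
                score = float(fields[4])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric score {fields[4]!r}") from None
        n_extra = max(n_extra, len(fields))
        rows.append((chrom, start, end, name, score))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score"])
    if n_extra <= 3:
        df = df.drop(columns=["name", "score"])
    elif n_extra == 4:
        df = df.drop(columns=["score"])
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in ["chrom", "start", "end", "name", "score"] if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_epi_table(path) -> pd.DataFrame:
    """Read an EPI-dialect TSV, validating every invariant of the dialect."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    missing = [c for c in EPI_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    df = df[EPI_COLUMNS]
    for col in ("start", "end", "tss"):
        if not np.issubdtype(df[col].dtype, np.integer):
            try:
                df[col] = df[col].astype(np.int64)
            except (ValueError, TypeError):
                raise FormatError(f"{path}: non-integer values in column {col}") from None
    if (df["start"] >= df["end"]).any():
        bad = df.index[df["start"] >= df["end"]][0]
        raise FormatError(f"{path}: row {bad}: start >= end")
    if (df["abc_score"] < 0).any():
        raise FormatError(f"{path}: negative abc_score")
    if (df["target_tpm"] < 0).any():
        raise FormatError(f"{path}: negative target_tpm")
    if not df["gene_strand"].isin(["+", "-"]).all():
        raise FormatError(f"{path}: gene_strand must be '+' or '-'")
    mid = (df["start"] + df["end"]) // 2
    if ((df["tss"] - mid).abs() > MAX_EPI_DISTANCE).any():
        raise FormatError(f"{path}: enhancer further than 5 Mb from its TSS")
    dup = df.duplicated(subset=["chrom", "start", "end", "target_gene", "cell_type"])
    if dup.any():
        warnings.warn(
            f"{path}: {int(dup.sum())} duplicate (enhancer, gene, cell_type) rows",
            stacklevel=2,
        )
    return df


def write_epi_table(records: pd.DataFrame, path) -> None:
    missing = [c for c in EPI_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"EPI frame missing column(s): {', '.join(missing)}")
    records[EPI_COLUMNS].to_csv(path, sep="\t", index=False)


def tf_from_motif(motif_id: str, motif_alt_id=None) -> str:
    """TF symbol for a FIMO motif row.

    Uses ``motif_alt_id`` when present (the MEME convention for the TF
    name); otherwise strips a trailing ``_...`` motif suffix from
    ``motif_id`` (e.g. ``SOX2_MA0143.4`` -> ``SOX2``).
    """
    if motif_alt_id is not None and isinstance(motif_alt_id, str) and motif_alt_id.strip():
        return motif_alt_id.strip()
    return motif_id.rsplit("_", 1)[0] if "_" in motif_id else motif_id


def read_fimo_tsv(path, p_threshold: float = 1e-5) -> pd.DataFrame:
    """Read FIMO's TSV output into a collapsed TF-binding table.

    Rows with p-value >= ``p_threshold`` are dropped (strictly-less-than
    filter), motifs of the same TF within the same enhancer are collapsed
    to a single row keeping the smallest p-value, and ``sequence_name``
    is parsed as a ``chrom:start-end`` enhancer identifier.

    Returns a frame with columns tf, chrom, start, end, p_value.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sequence_name": str})
    return collapse_fimo_frame(df, p_threshold=p_threshold, source=str(path))


def collapse_fimo_frame(
    df: pd.DataFrame, p_threshold: float = 1e-5, source: str = "<frame>"
) -> pd.DataFrame:
    """Filter and motif-collapse an in-memory FIMO frame (see
    :func:`read_fimo_tsv`)."""
    path = source
    missing = [c for c in _FIMO_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing FIMO column(s): {', '.join(missing)}")
    df = df[df["p-value"] < p_threshold]
    if df.empty:
        return pd.DataFrame(columns=["tf", "chrom", "start", "end", "p_value"])
    parsed = df["sequence_name"].str.extract(_SEQNAME_RE)
    if parsed["chrom"].isna().any():
        bad = df["sequence_name"][parsed["chrom"].isna()].iloc[0]
        raise FormatError(
            f"{path}: sequence_name {bad!r} is not of the form chrom:start-end"
        )
    alt = df["motif_alt_id"] if "motif_alt_id" in df.columns else pd.Series(None, index=df.index)
    out = pd.DataFrame(
        {
            "tf": [tf_from_motif(m, a) for m, a in zip(df["motif_id"], alt)],
            "chrom": parsed["chrom"].to_numpy(),
            "start": parsed["start"].astype(np.int64).to_numpy(),
            "end": parsed["end"].astype(np.int64).to_numpy(),
            "p_value": df["p-value"].to_numpy(),
        }
    )
    out = (
        out.sort_values("p_value", kind="stable")
        .drop_duplicates(subset=["tf", "chrom", "start", "end"], keep="first")
        .sort_index()
        .reset_index(drop=True)
    )
    return out


def read_tpm_table(path) -> dict[str, float]:
    """Read a two-column (gene, TPM) TSV into a mapping."""
    tpm: dict[str, float] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 2:
            raise FormatError(f"{path}:{lineno}: expected exactly 2 columns")
        gene, value = fields
        if gene in tpm:
            raise FormatError(f"{path}:{lineno}: duplicate gene {gene!r}")
        try:
            tpm[gene] = float(value)
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-numeric TPM {value!r}") from None
    return tpm


def write_tpm_table(tpm: dict[str, float], path) -> None:
    # full repr so that write/read round-trips exactly
    with open(path, "w", encoding="utf-8") as fh:
        for gene, value in tpm.items():
            fh.write(f"{gene}\t{value!r}\n")


def read_gene_list(path) -> set[str]:
    """Read a one-gene-per-line list; matching downstream is exact,
    full-symbol (the behaviour of ``grep -x``)."""
    genes = set()
    for _, line in _data_lines(path):
        genes.add(line.strip())
    genes.discard("")
    return genes


def write_gene_list(genes, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")
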