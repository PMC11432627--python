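"""Synthetic inputs with the statistical structure the pipeline assumes.

The generator emulates the six-cell-type neural differentiation design:
three progenitor cell types (ESC, NSC, NPC) and three mature neuron
types (AD, Ngn2, Motor).  Enhancers are 500-bp elements laid out on a
non-overlapping genomic grid and assigned, by construction rather than
by sampling labels post hoc, to one of three sharing classes:

* *cell-type-specific* — present in exactly one cell type;
* *stage-shared* — present in all three cell types of one stage;
* *ubiquitous* — present in all six cell types.

Shared enhancers are written at identical coordinates across cell types
by default (an optional jitter of <= 100 bp exercises the 100-bp subset
merge).  Every planted signal — sharing fractions, TF stage bias,
variant enrichment in a chosen sub-structure, differential-expression
direction, disease-gene overlap — is recorded in a ground-truth
manifest so downstream modules can be scored on parameter recovery.

ABC scores and TPMs are drawn directly (mixtures straddling the 0.02
score and 1-TPM filter boundaries) so network-level modules are
testable independently of the scoring module; ``generate_peak_counts``
provides the complementary end-to-end mode that emits peak read counts
for the scoring module to consume.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .celltypes import CELL_TYPES, STAGE_OF, validate_stage_map
from .io_formats import (
    EPI_COLUMNS,
    write_bed,
    write_epi_table,
    write_gene_list,
    write_tpm_table,
)
from .network_builder import SUBSTRUCTURES

#: Grid pitch between candidate enhancer slots (bp).  Slots are 1 kb
#: apart and enhancers 500 bp wide, so distinct slots can never overlap
#: and never fall within 100 bp of each other, even under maximal jitter.
SLOT_PITCH = 1000
SLOT_OFFSET = 250
ENHANCER_WIDTH = 500
MAX_JITTER = 100

SHARING_CLASSES = ("cell_type_specific", "stage_shared", "ubiquitous")


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic study.

    The defaults describe a compact version of the study design: six
    cell types in two stage groups, 35% cell-type-specific enhancers
    (the sharing level reported for the real networks), 25% stage-shared
    and the rest ubiquitous, ABC scores and TPMs straddling the 0.02 /
    1-TPM filter boundaries, and ~250k-style case/control single-base
    variant sets scaled to the synthetic genome.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 2_000_000
    cell_types: tuple[str, ...] = CELL_TYPES
    stage_map: dict[str, str] = field(default_factory=lambda: dict(STAGE_OF))
    n_enhancers_per_celltype: int = 300
    frac_celltype_specific_enh: float = 0.35
    frac_stage_shared_enh: float = 0.25
    jitter_bp: int = 0
    n_genes: int = 200
    min_links_per_enhancer: int = 1
    max_links_per_enhancer: int = 2
    frac_abc_below_threshold: float = 0.2
    abc_score_max: float = 0.5
    frac_tpm_below_1: float = 0.2
    n_tfs: int = 60
    tf_stage_bias: float = 0.6
    tf_bind_prob: float = 0.12
    frac_weak_tfbs: float = 0.1
    frac_second_motif: float = 0.1
    n_case_variants: int = 5000
    n_control_variants: int = 5000
    planted_substructure: str | None = None
    planted_odds: float = 1.0
    n_de_genes_per_direction: int = 20
    n_disease_genes: int = 40
    frac_disease_gene_overlap: float = 0.5
    disease_target_celltypes: tuple[str, ...] = ("NPC", "AD")

    def __post_init__(self) -> None:
        validate_stage_map(self.cell_types, self.stage_map)
        if not (0 <= self.frac_celltype_specific_enh <= 1):
            raise ValueError("frac_celltype_specific_enh must be in [0, 1]")
        if not (0 <= self.frac_stage_shared_enh <= 1):
            raise ValueError("frac_stage_shared_enh must be in [0, 1]")
        if self.frac_celltype_specific_enh + self.frac_stage_shared_enh > 1:
            raise ValueError("sharing fractions sum to more than 1")
        if self.n_chromosomes < 1:
            raise ValueError("n_chromosomes must be >= 1")
        if self.chrom_length <= 0:
            raise ValueError("chrom_length must be positive")
        if self.chrom_length < 100_000:
            raise ValueError("chrom_length must be >= 100000 bp")
        if not (0 <= self.jitter_bp <= MAX_JITTER):
            raise ValueError(f"jitter_bp must be in [0, {MAX_JITTER}]")
        if self.planted_substructure is not None and (
            self.planted_substructure not in SUBSTRUCTURES
        ):
            raise ValueError(
                f"planted_substructure must be one of {SUBSTRUCTURES} or None"
            )
        if self.planted_odds < 1:
            raise ValueError("planted_odds must be >= 1")
        if not (0 <= self.tf_stage_bias <= 1):
            raise ValueError("tf_stage_bias must be in [0, 1]")
        if self.min_links_per_enhancer < 1:
            raise ValueError("min_links_per_enhancer must be >= 1")
        if self.max_links_per_enhancer < self.min_links_per_enhancer:
            raise ValueError("max_links_per_enhancer < min_links_per_enhancer")

    @property
    def progenitor(self) -> list[str]:
        return [c for c in self.cell_types if self.stage_map[c] == "progenitor"]

    @property
    def mature(self) -> list[str]:
        return [c for c in self.cell_types if self.stage_map[c] == "mature"]

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("cell_types", "disease_target_celltypes"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class GroundTruthManifest:
    """Planted signals of one synthetic study, sufficient to score the
    recovery of every parameter downstream."""

    sharing_fractions: dict[str, float]
    enhancer_sharing: pd.DataFrame  # enh_id, chrom, start, end, sharing_class, owner
    tf_bias: pd.DataFrame | None = None  # tf, archetype
    variant_truth: pd.DataFrame | None = None  # variant index, label, planted_target
    de_truth: pd.DataFrame | None = None  # gene, planted direction
    disease_gene_truth: pd.DataFrame | None = None  # gene, from_targets

    def to_json(self, path) -> None:
        payload = {
            "sharing_fractions": self.sharing_fractions,
            "enhancer_sharing": self.enhancer_sharing.to_dict(orient="list"),
        }
        for name in ("tf_bias", "variant_truth", "de_truth", "disease_gene_truth"):
            df = getattr(self, name)
            payload[name] = None if df is None else df.to_dict(orient="list")
        def _tolerant(obj):
            if hasattr(obj, "item"):
                return obj.item()  # numpy scalar
            raise TypeError(f"not JSON-serializable: {type(obj)}")

        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, default=_tolerant)


@dataclass
class SyntheticDataset:
    """All generated tables of one synthetic study plus its manifest."""

    config: SyntheticConfig
    genome: pd.DataFrame
    genes: pd.DataFrame
    enhancers: pd.DataFrame
    epi_tables: dict[str, pd.DataFrame]
    tpm: pd.DataFrame
    manifest: GroundTruthManifest


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def generate_genome(config: SyntheticConfig) -> pd.DataFrame:
    """Chromosome size table: chr1..chrN of the configured length."""
    if config.n_chromosomes < 1 or config.chrom_length <= 0:
        raise ValueError("genome dimensions must be positive")
    return pd.DataFrame(
        {
            "chrom": [f"chr{i + 1}" for i in range(config.n_chromosomes)],
            "length": np.full(config.n_chromosomes, config.chrom_length, dtype=np.int64),
        }
    )


def _class_counts(config: SyntheticConfig) -> tuple[int, int, int]:
    n = config.n_enhancers_per_celltype
    n_spec = round(config.frac_celltype_specific_enh * n)
    n_stage = round(config.frac_stage_shared_enh * n)
    n_ubi = n - n_spec - n_stage
    if n_ubi < 0:
        raise ValueError("sharing fractions infeasible for this enhancer count")
    return n_spec, n_stage, n_ubi


def generate_epi_tables(
    config: SyntheticConfig, genome: pd.DataFrame
) -> SyntheticDataset:
    """Generate per-cell-type EPI tables and the ground-truth manifest.

    Enhancers are placed on a 1-kb slot grid (500-bp elements, so
    distinct slots never overlap); sharing classes are assigned exactly
    at the configured counts.  Each enhancer archetype links to 1-2
    genes within 5 Mb on its chromosome; ABC scores and per-cell-type
    TPMs are drawn from mixtures with the configured fractions below the
    0.02 and 1-TPM filter boundaries.
    """
    rng = _rng(config, 1)
    n_spec, n_stage, n_ubi = _class_counts(config)
    cts = list(config.cell_types)
    stages = ("progenitor", "mature")
    by_stage = {s: [c for c in cts if config.stage_map[c] == s] for s in stages}

    n_archetypes = n_ubi + len(stages) * n_stage + len(cts) * n_spec
    slots_per_chrom = (config.chrom_length - SLOT_OFFSET - ENHANCER_WIDTH - MAX_JITTER) // SLOT_PITCH
    total_slots = config.n_chromosomes * slots_per_chrom
    if n_archetypes > total_slots:
        raise ValueError(
            f"need {n_archetypes} enhancer slots but the genome only has {total_slots}"
        )
    slot_ids = rng.choice(total_slots, size=n_archetypes, replace=False)
    chrom_idx = slot_ids // slots_per_chrom
    starts = SLOT_OFFSET + (slot_ids % slots_per_chrom) * SLOT_PITCH
    chroms = genome["chrom"].to_numpy()[chrom_idx]

    sharing = np.empty(n_archetypes, dtype=object)
    owner = np.empty(n_archetypes, dtype=object)
    sharing[:n_ubi] = "ubiquitous"
    owner[:n_ubi] = "all"
    pos = n_ubi
    for s in stages:
        sharing[pos : pos + n_stage] = "stage_shared"
        owner[pos : pos + n_stage] = s
        pos += n_stage
    for ct in cts:
        sharing[pos : pos + n_spec] = "cell_type_specific"
        owner[pos : pos + n_spec] = ct
        pos += n_spec

    enhancers = pd.DataFrame(
        {
            "enh_id": [f"E{i:06d}" for i in range(n_archetypes)],
            "chrom": chroms,
            "start": starts.astype(np.int64),
            "end": (starts + ENHANCER_WIDTH).astype(np.int64),
            "sharing_class": sharing,
            "owner": owner,
        }
    )

    # genes: uniform positions, random strand, TSS = start (+) or end (-)
    genes_per_chrom = np.full(config.n_chromosomes, config.n_genes // config.n_chromosomes)
    genes_per_chrom[: config.n_genes % config.n_chromosomes] += 1
    g_chrom, g_start, g_end, g_strand = [], [], [], []
    for ci, n_g in enumerate(genes_per_chrom):
        s = rng.integers(5000, config.chrom_length - 30_000, size=n_g)
        length = rng.integers(2000, 20_000, size=n_g)
        g_chrom.extend([genome["chrom"].iloc[ci]] * int(n_g))
        g_start.extend(s.tolist())
        g_end.extend((s + length).tolist())
        g_strand.extend(np.where(rng.random(n_g) < 0.5, "+", "-").tolist())
    genes = pd.DataFrame(
        {
            "gene": [f"GENE{i + 1:05d}" for i in range(config.n_genes)],
            "chrom": g_chrom,
            "start": np.asarray(g_start, dtype=np.int64),
            "end": np.asarray(g_end, dtype=np.int64),
            "strand": g_strand,
        }
    )
    genes["tss"] = np.where(genes["strand"] == "+", genes["start"], genes["end"])

    # per-cell-type TPM with the configured fraction below 1
    low = rng.random((config.n_genes, len(cts))) < config.frac_tpm_below_1
    tpm_vals = np.where(
        low,
        rng.uniform(0.01, 0.99, size=low.shape),
        10 ** rng.uniform(0.05, 2.5, size=low.shape),
    )
    tpm = pd.DataFrame(tpm_vals, index=genes["gene"], columns=cts)

    # enhancer -> gene links within the 5-Mb window, shared across the
    # cell types the enhancer is present in
    links = _draw_links(config, rng, enhancers, genes)

    presence = _presence_map(config, enhancers, by_stage)
    epi_tables = {}
    for ct in cts:
        arch_rows = links[links["enh_id"].isin(presence[ct])]
        m = len(arch_rows)
        below = rng.random(m) < config.frac_abc_below_threshold
        score = np.where(
            below,
            rng.uniform(0.001, 0.0199, size=m),
            rng.uniform(0.02, config.abc_score_max, size=m),
        )
        start = arch_rows["start"].to_numpy().copy()
        if config.jitter_bp > 0:
            start = start + rng.integers(
                -config.jitter_bp, config.jitter_bp + 1, size=m
            )
        table = pd.DataFrame(
            {
                "chrom": arch_rows["chrom"].to_numpy(),
                "start": start,
                "end": start + ENHANCER_WIDTH,
                "cell_type": ct,
                "target_gene": arch_rows["gene"].to_numpy(),
                "tss": arch_rows["tss"].to_numpy(),
                "gene_strand": arch_rows["strand"].to_numpy(),
                "abc_score": score,
                "target_tpm": tpm.loc[arch_rows["gene"], ct].to_numpy(),
            }
        )[EPI_COLUMNS]
        epi_tables[ct] = table.reset_index(drop=True)

    n_total = float(n_spec + n_stage + n_ubi)
    manifest = GroundTruthManifest(
        sharing_fractions={
            "cell_type_specific": n_spec / n_total,
            "stage_shared": n_stage / n_total,
            "ubiquitous": n_ubi / n_total,
        },
        enhancer_sharing=enhancers.copy(),
    )
    return SyntheticDataset(
        config=config,
        genome=genome,
        genes=genes,
        enhancers=enhancers,
        epi_tables=epi_tables,
        tpm=tpm,
        manifest=manifest,
    )


def _draw_links(config, rng, enhancers, genes) -> pd.DataFrame:
    """One row per (enhancer archetype, target gene) link."""
    frames = []
    for chrom, enh_c in enhancers.groupby("chrom", sort=False):
        gs = genes[genes["chrom"] == chrom].sort_values("tss")
        if gs.empty:
            raise ValueError(f"no gene on {chrom}; increase n_genes")
        tss_sorted = gs["tss"].to_numpy()
        mid = (enh_c["start"].to_numpy() + enh_c["end"].to_numpy()) // 2
        lo = np.searchsorted(tss_sorted, mid - 5_000_000, side="left")
        hi = np.searchsorted(tss_sorted, mid + 5_000_000, side="right")
        if (hi <= lo).any():
            raise ValueError(f"enhancer on {chrom} has no gene within 5 Mb")
        n_links = rng.integers(
            config.min_links_per_enhancer,
            config.max_links_per_enhancer + 1,
            size=len(enh_c),
        )
        rep = np.repeat(np.arange(len(enh_c)), n_links)
        pick = lo[rep] + (rng.random(rep.size) * (hi[rep] - lo[rep])).astype(np.int64)
        frame = pd.DataFrame(
            {
                "enh_id": enh_c["enh_id"].to_numpy()[rep],
                "chrom": chrom,
                "start": enh_c["start"].to_numpy()[rep],
                "end": enh_c["end"].to_numpy()[rep],
                "gene": gs["gene"].to_numpy()[pick],
                "tss": gs["tss"].to_numpy()[pick],
                "strand": gs["strand"].to_numpy()[pick],
            }
        )
        frames.append(frame)
    links = pd.concat(frames, ignore_index=True)
    return links.drop_duplicates(subset=["enh_id", "gene"]).reset_index(drop=True)


def _presence_map(config, enhancers, by_stage) -> dict[str, set]:
    """Cell type -> set of enhancer archetype ids present in it."""
    presence = {ct: set() for ct in config.cell_types}
    for row in enhancers.itertuples(index=False):
        if row.sharing_class == "ubiquitous":
            for ct in config.cell_types:
                presence[ct].add(row.enh_id)
        elif row.sharing_class == "stage_shared":
            for ct in by_stage[row.owner]:
                presence[ct].add(row.enh_id)
        else:
            presence[row.owner].add(row.enh_id)
    return presence


def generate_tfbs_table(
    config: SyntheticConfig, dataset: SyntheticDataset
) -> pd.DataFrame:
    """FIMO-style TFBS table with planted TF stage-bias archetypes.

    TFs split into three archetypes (progenitor-biased, mature-biased,
    unbiased); a biased TF binds enhancers on its own stage's side with
    probability ``p0 * (1 + bias)`` and the opposite side with ``p0 *
    (1 - bias)`` (ubiquitous enhancers at ``p0``).  A configured
    fraction of rows gets p-values failing the strict 1e-5 filter, and
    a fraction of bound pairs emits a second motif row for the same TF
    to exercise motif-to-TF collapsing.  The archetype of every TF is
    recorded in the manifest.
    """
    if config.n_tfs < 3:
        raise ValueError("n_tfs must be >= 3 (k-means with k=3)")
    rng = _rng(config, 2)
    enh = dataset.enhancers
    n_tfs, n_enh = config.n_tfs, len(enh)
    third = n_tfs // 3
    archetype = np.array(
        ["progenitor"] * third
        + ["mature"] * third
        + ["uniform"] * (n_tfs - 2 * third),
        dtype=object,
    )
    tfs = np.array([f"TF{i + 1:04d}" for i in range(n_tfs)], dtype=object)

    # enhancer stage side: the stage whose cell types carry it (None for ubiquitous)
    side = np.where(
        enh["sharing_class"] == "ubiquitous",
        "none",
        np.where(
            enh["sharing_class"] == "stage_shared",
            enh["owner"],
            enh["owner"].map(config.stage_map).fillna("none"),
        ),
    )
    p0, b = config.tf_bind_prob, config.tf_stage_bias
    prob = np.full((n_tfs, n_enh), p0)
    for i, arch in enumerate(archetype):
        if arch == "uniform":
            continue
        own = side == arch
        other = (side != arch) & (side != "none")
        prob[i, own] = min(p0 * (1 + b), 1.0)
        prob[i, other] = p0 * (1 - b)
    bound = rng.random((n_tfs, n_enh)) < prob
    tf_idx, enh_idx = np.nonzero(bound)
    m = tf_idx.size

    weak = rng.random(m) < config.frac_weak_tfbs
    log_p = np.where(
        weak, rng.uniform(-5.0, -3.0, size=m), rng.uniform(-9.0, -5.0001, size=m)
    )
    second = rng.random(m) < config.frac_second_motif

    seq = (
        enh["chrom"].astype(str)
        + ":"
        + enh["start"].astype(str)
        + "-"
        + enh["end"].astype(str)
    ).to_numpy()
    def _rows(t_idx, e_idx, motif_suffix, logp):
        k = t_idx.size
        offset = rng.integers(1, ENHANCER_WIDTH - 25, size=k)
        return pd.DataFrame(
            {
                "motif_id": [f"{t}_{motif_suffix}" for t in tfs[t_idx]],
                "motif_alt_id": tfs[t_idx],
                "sequence_name": seq[e_idx],
                "start": offset,
                "stop": offset + 15,
                "strand": np.where(rng.random(k) < 0.5, "+", "-"),
                "score": np.round(rng.uniform(8, 25, size=k), 3),
                "p-value": 10.0 ** logp,
                "q-value": np.nan,
                "matched_sequence": "N" * 15,
            }
        )

    frames = [_rows(tf_idx, enh_idx, "m1", log_p)]
    if second.any():
        frames.append(
            _rows(
                tf_idx[second],
                enh_idx[second],
                "m2",
                np.maximum(log_p[second], -8.5),
            )
        )
    fimo = pd.concat(frames, ignore_index=True)
    dataset.manifest.tf_bias = pd.DataFrame({"tf": tfs, "archetype": archetype})
    return fimo


def generate_variant_sets(
    config: SyntheticConfig,
    dataset: SyntheticDataset,
    element_categories: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Case and control single-base variant sets, optionally with a
    planted enrichment.

    Control variants are uniform over the genome.  Case variants are
    uniform too unless ``planted_substructure`` is set, in which case
    their odds of falling inside an element of that category are
    ``planted_odds`` times the uniform odds: each case variant is
    placed inside a random target element with probability
    ``m*f / (1 - f + m*f)`` (f = genomic fraction covered by the target
    elements, m = odds multiplier) and uniformly outside them otherwise.
    """
    from .intervals import merge_intervals, overlaps_any

    rng = _rng(config, 3)
    genome = dataset.genome
    lengths = genome["length"].to_numpy()
    total = lengths.sum()

    def _uniform(n):
        pos = rng.integers(0, total, size=n)
        cum = np.cumsum(lengths)
        ci = np.searchsorted(cum, pos, side="right")
        offs = pos - np.concatenate(([0], cum[:-1]))[ci]
        return pd.DataFrame(
            {
                "chrom": genome["chrom"].to_numpy()[ci],
                "start": offs.astype(np.int64),
                "end": offs.astype(np.int64) + 1,
            }
        )

    control = _uniform(config.n_control_variants)
    if config.planted_substructure is None or config.planted_odds == 1.0:
        case = _uniform(config.n_case_variants)
        planted = np.zeros(len(case), dtype=bool)
    else:
        if element_categories is None:
            raise ValueError(
                "planted enrichment requires the element-category table"
            )
        target = element_categories[
            element_categories["category"] == config.planted_substructure
        ]
        if target.empty:
            raise ValueError(
                f"sub-structure {config.planted_substructure} absent from the networks"
            )
        merged, _ = merge_intervals(target[["chrom", "start", "end"]], gap=0)
        widths = (merged["end"] - merged["start"]).to_numpy()
        f = widths.sum() / total
        m = config.planted_odds
        p_in = m * f / (1 - f + m * f)
        n_case = config.n_case_variants
        planted = rng.random(n_case) < p_in
        n_in = int(planted.sum())
        # inside: element chosen with probability proportional to width
        elem = rng.choice(len(merged), size=n_in, p=widths / widths.sum())
        inside_pos = merged["start"].to_numpy()[elem] + (
            rng.random(n_in) * widths[elem]
        ).astype(np.int64)
        inside = pd.DataFrame(
            {
                "chrom": merged["chrom"].to_numpy()[elem],
                "start": inside_pos,
                "end": inside_pos + 1,
            }
        )
        # outside: uniform with rejection of target-element hits
        n_out = n_case - n_in
        outside = _uniform(n_out)
        for _ in range(50):
            bad = overlaps_any(outside, merged)
            if not bad.any():
                break
            outside.loc[bad, ["chrom", "start", "end"]] = _uniform(
                int(bad.sum())
            ).to_numpy()
        case = pd.concat([inside, outside], ignore_index=True)
        order = rng.permutation(len(case))
        case = case.iloc[order].reset_index(drop=True)
        planted = np.concatenate([np.ones(n_in, bool), np.zeros(n_out, bool)])[order]

    dataset.manifest.variant_truth = pd.DataFrame(
        {
            "label": ["case"] * len(case) + ["control"] * len(control),
            "planted_target": np.concatenate(
                [
                    np.where(planted, config.planted_substructure or "background", "background"),
                    np.full(len(control), "background", dtype=object),
                ]
            ),
        }
    )
    return case, control


@dataclass
class ExpressionBundle:
    """TPM tables, a planted DE contrast (ESC vs NPC), and a disease gene list."""

    tpm_tables: dict[str, dict[str, float]]
    de_table: pd.DataFrame  # gene, lfc, fdr
    disease_genes: set[str]


def generate_expression_and_genesets(
    config: SyntheticConfig, dataset: SyntheticDataset
) -> ExpressionBundle:
    """Two-column TPM tables, a DE table with planted direction, and a
    disease gene list with a planted target-gene overlap fraction.

    The DE contrast follows the ESC-vs-NPC design: planted up genes
    (LFC > 1, FDR < 0.05) are drawn preferentially from NPC-network
    target genes, planted down genes (LFC < -1) from ESC-network
    targets; all other genes get null LFC/FDR.  The disease list mixes
    target genes of the configured cell types with external symbols at
    the configured overlap fraction.
    """
    rng = _rng(config, 4)
    genes = dataset.genes["gene"].to_numpy()
    tpm_tables = {
        ct: dict(zip(dataset.tpm.index, dataset.tpm[ct].round(6)))
        for ct in config.cell_types
    }

    # TF genes are expressed too: biased TFs peak in their own stage so
    # the expression grouping can recover the planted archetype
    if dataset.manifest.tf_bias is not None:
        b = config.tf_stage_bias
        for tf, arch in zip(
            dataset.manifest.tf_bias["tf"], dataset.manifest.tf_bias["archetype"]
        ):
            base = float(10 ** rng.uniform(0.5, 1.5))
            for ct in config.cell_types:
                boost = 1.0
                if arch != "uniform" and b > 0:
                    boost = 1 + 2 * b if config.stage_map[ct] == arch else 1 / (1 + 2 * b)
                tpm_tables[ct][tf] = round(base * boost * float(rng.uniform(0.9, 1.1)), 6)

    npc_targets = set(dataset.epi_tables.get("NPC", pd.DataFrame(columns=["target_gene"]))["target_gene"])
    esc_targets = set(dataset.epi_tables.get("ESC", pd.DataFrame(columns=["target_gene"]))["target_gene"])
    npc_only = sorted(npc_targets - esc_targets) or sorted(npc_targets)
    esc_only = sorted(esc_targets - npc_targets) or sorted(esc_targets)
    n_dir = config.n_de_genes_per_direction
    up = set(rng.choice(npc_only, size=min(n_dir, len(npc_only)), replace=False)) if npc_only else set()
    down_pool = [g for g in esc_only if g not in up]
    down = set(rng.choice(down_pool, size=min(n_dir, len(down_pool)), replace=False)) if down_pool else set()

    lfc = rng.normal(0, 0.3, size=len(genes))
    fdr = rng.uniform(0, 1, size=len(genes))
    direction = np.full(len(genes), "null", dtype=object)
    for i, g in enumerate(genes):
        if g in up:
            lfc[i] = 1.2 + abs(rng.normal(0.8, 0.5))
            fdr[i] = rng.uniform(1e-6, 0.049)
            direction[i] = "up"
        elif g in down:
            lfc[i] = -(1.2 + abs(rng.normal(0.8, 0.5)))
            fdr[i] = rng.uniform(1e-6, 0.049)
            direction[i] = "down"
    de_table = pd.DataFrame({"gene": genes, "lfc": lfc, "fdr": fdr})

    target_pool = sorted(
        set().union(
            *(
                set(dataset.epi_tables[ct]["target_gene"])
                for ct in config.disease_target_celltypes
                if ct in dataset.epi_tables
            )
        )
    )
    n_overlap = round(config.frac_disease_gene_overlap * config.n_disease_genes)
    n_overlap = min(n_overlap, len(target_pool))
    from_targets = (
        list(rng.choice(target_pool, size=n_overlap, replace=False)) if n_overlap else []
    )
    externals = [f"EXT{i + 1:04d}" for i in range(config.n_disease_genes - n_overlap)]
    disease = set(from_targets) | set(externals)

    dataset.manifest.de_truth = pd.DataFrame({"gene": genes, "direction": direction})
    dataset.manifest.disease_gene_truth = pd.DataFrame(
        {
            "gene": from_targets + externals,
            "from_targets": [True] * len(from_targets) + [False] * len(externals),
        }
    )
    return ExpressionBundle(tpm_tables=tpm_tables, de_table=de_table, disease_genes=disease)


def generate_peak_counts(
    config: SyntheticConfig, dataset: SyntheticDataset, cell_type: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """End-to-end mode: ATAC and H3K27ac peak read counts over the cell
    type's enhancer regions, for the scoring module to consume."""
    rng = _rng(config, 5)
    table = dataset.epi_tables[cell_type]
    peaks = table[["chrom", "start", "end"]].drop_duplicates().reset_index(drop=True)
    n = len(peaks)
    atac = peaks.assign(score=np.round(rng.lognormal(4.0, 0.8, size=n), 1))
    h3k = peaks.assign(score=np.round(rng.lognormal(4.5, 0.9, size=n), 1))
    return atac, h3k


def write_dataset(dataset: SyntheticDataset, outdir, bundle: ExpressionBundle | None = None,
                  fimo: pd.DataFrame | None = None,
                  case: pd.DataFrame | None = None,
                  control: pd.DataFrame | None = None) -> None:
    """Write every generated table under ``outdir`` in its external format."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    dataset.genome.to_csv(out / "genome.tsv", sep="\t", index=False)
    dataset.genes[["chrom", "start", "end", "gene", "strand"]].to_csv(
        out / "genes.bed", sep="\t", header=False, index=False
    )
    for ct, table in dataset.epi_tables.items():
        write_epi_table(table, out / f"epi_{ct}.tsv")
    if bundle is not None:
        for ct, tpm in bundle.tpm_tables.items():
            write_tpm_table(tpm, out / f"tpm_{ct}.tsv")
        bundle.de_table.to_csv(out / "de_table.tsv", sep="\t", index=False)
        write_gene_list(bundle.disease_genes, out / "disease_genes.txt")
    if fimo is not None:
        fimo.to_csv(out / "fimo.tsv", sep="\t", index=False)
    if case is not None:
        write_bed(case, out / "case_variants.bed")
    if control is not None:
        write_bed(control, out / "control_variants.bed")
    dataset.manifest.to_json(out / "manifest.json")
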