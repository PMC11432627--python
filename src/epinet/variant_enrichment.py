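"""Variant/gene-set enrichment over EPI networks.

Three statistical procedures:

* an *empirical resampling test*: the number of a cell type's elements
  (enhancers, 2-kb promoter regions, or target genes) carrying at least
  one variant is compared with the counts obtained by drawing
  size-matched element sets, without replacement, from the deduplicated
  collapsed-network pool; the upper-tail empirical p is
  ``(1 + #{null >= observed}) / (R + 1)``;
* *Fisher's exact test* on 2x2 tables (scipy's exact hypergeometric
  p-value; conditional maximum-likelihood odds ratio by default);
* per-sub-structure case/control contrasts: variants are attributed to
  the sub-structure categories of the elements they fall in, and each
  category is contrasted against all others in a case-vs-control 2x2.

Significance uses the corrected threshold 0.05 / 6 = 0.008333 for the
six per-cell-type tests and 0.05 for nominal significance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact as _scipy_fisher
from scipy.stats.contingency import odds_ratio as _scipy_odds_ratio

from .intervals import overlaps_any
from .network_builder import ENHANCER_KEY, EPINetwork, SUBSTRUCTURES, substructure_elements

NOMINAL_ALPHA = 0.05
DEFAULT_REPS = 1000
PROMOTER_UPSTREAM = 2000


def corrected_threshold(n_tests: int = 6, alpha: float = NOMINAL_ALPHA) -> float:
    """Multiple-testing-corrected threshold for the per-cell-type tests,
    rounded to 6 decimals (0.05 / 6 -> 0.008333)."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return round(alpha / n_tests, 6)


@dataclass
class EnrichmentResult:
    """Outcome of one empirical resampling enrichment test."""

    cell_type: str
    element_kind: str
    observed: int
    null_counts: np.ndarray
    p_empirical: float
    significant: bool
    nominal: bool


@dataclass
class FisherResult:
    """A 2x2 exact-test outcome."""

    table: np.ndarray
    odds_ratio: float
    p_two_sided: float


def derive_promoter_regions(
    genes: pd.DataFrame, chrom_sizes: dict[str, int] | None = None
) -> pd.DataFrame:
    """Strand-aware 2000-bp promoter regions from a gene annotation.

    ``genes`` needs columns chrom, start, end, strand, gene.  On the +
    strand the promoter is the 2000 bp upstream of the start coordinate,
    ``[start - 2000, start)``; on the - strand it is the 2000 bp
    downstream of the end coordinate, ``[end, end + 2000)``.  Regions
    are clipped to ``[0, chrom length]``; genes whose clipped promoter
    is empty are dropped with a warning.
    """
    unknown = ~genes["strand"].isin(["+", "-"])
    if unknown.any():
        raise ValueError(
            f"unknown strand for gene(s): {genes['gene'][unknown].tolist()[:5]}"
        )
    plus = genes["strand"] == "+"
    start = np.where(plus, genes["start"] - PROMOTER_UPSTREAM, genes["end"])
    end = np.where(plus, genes["start"], genes["end"] + PROMOTER_UPSTREAM)
    clipped = np.flatnonzero(start < 0)
    start = np.maximum(start, 0)
    if chrom_sizes is not None:
        limits = genes["chrom"].map(chrom_sizes).to_numpy()
        end = np.minimum(end, limits)
    out = pd.DataFrame(
        {
            "gene": genes["gene"].to_numpy(),
            "chrom": genes["chrom"].to_numpy(),
            "start": start.astype(np.int64),
            "end": end.astype(np.int64),
        }
    )
    empty = out["start"] >= out["end"]
    if clipped.size or empty.any():
        warnings.warn(
            f"{clipped.size} promoter region(s) clipped at a chromosome edge; "
            f"{int(empty.sum())} empty after clipping (dropped)",
            stacklevel=2,
        )
    return out[~empty].reset_index(drop=True)


def count_elements_with_variant(
    elements: pd.DataFrame, variants: pd.DataFrame
) -> int:
    """Number of elements containing >= 1 variant (each element counted once)."""
    return int(overlaps_any(elements, variants).sum())


def _draw_null_counts(
    bearing: np.ndarray, k: int, reps: int, rng: np.random.Generator
) -> np.ndarray:
    """Counts of variant-bearing elements in ``reps`` uniform draws of
    ``k`` elements without replacement from a pool with per-element
    bearing flags."""
    n = bearing.size
    if k == n:
        return np.full(reps, bearing.sum(), dtype=int)
    if reps * n <= 20_000_000:
        # vectorized: k smallest of a random key per row = uniform subset
        keys = rng.random((reps, n))
        picks = np.argpartition(keys, k - 1, axis=1)[:, :k]
        return bearing[picks].sum(axis=1)
    counts = np.empty(reps, dtype=int)
    for r in range(reps):
        counts[r] = bearing[rng.choice(n, size=k, replace=False)].sum()
    return counts


def empirical_enrichment_test(
    target,
    pool,
    variants_or_geneset,
    element_kind: str,
    reps: int = DEFAULT_REPS,
    seed: int = 0,
    cell_type: str = "",
    n_tests: int = 6,
    legacy_p: bool = False,
) -> EnrichmentResult:
    """Empirical resampling enrichment of variants (or genes) in a
    cell type's elements relative to the collapsed-network pool.

    For interval kinds (``enhancer``/``promoter``) ``target`` and
    ``pool`` are interval frames and ``variants_or_geneset`` an interval
    frame of variants; for ``gene`` they are symbol collections and a
    gene set (exact full-symbol matching).  Elements are deduplicated
    (exact interval / exact symbol).  ``reps`` size-matched draws without
    replacement from the pool give the null counts; the default p is the
    add-one upper-tail estimator ``(1 + #{null >= obs})/(reps + 1)``;
    ``legacy_p`` reproduces the plain ``#{null >= obs}/reps`` ratio.
    """
    rng = np.random.default_rng(seed)
    if element_kind == "gene":
        target_set = set(target)
        pool_list = sorted(set(pool))
        geneset = set(variants_or_geneset)
        if len(target_set) > len(pool_list):
            raise ValueError(
                f"target has {len(target_set)} genes but pool only {len(pool_list)}"
            )
        if len(target_set) == 0:
            raise ValueError("empty target set")
        observed = len(target_set & geneset)
        bearing = np.array([g in geneset for g in pool_list])
    elif element_kind in ("enhancer", "promoter"):
        target_df = target[ENHANCER_KEY].drop_duplicates().reset_index(drop=True)
        pool_df = pool[ENHANCER_KEY].drop_duplicates().reset_index(drop=True)
        variants = variants_or_geneset
        if len(variants) == 0:
            raise ValueError("empty variant set")
        if len(target_df) > len(pool_df):
            raise ValueError(
                f"target has {len(target_df)} elements but pool only {len(pool_df)}"
            )
        if len(target_df) == 0:
            raise ValueError("empty target set")
        observed = count_elements_with_variant(target_df, variants)
        bearing = overlaps_any(pool_df, variants)
    else:
        raise ValueError("element_kind must be 'enhancer', 'promoter' or 'gene'")

    k = len(target_set) if element_kind == "gene" else len(target_df)
    null_counts = _draw_null_counts(np.asarray(bearing), k, reps, rng)
    n_ge = int((null_counts >= observed).sum())
    p = n_ge / reps if legacy_p else (1 + n_ge) / (reps + 1)
    thr = corrected_threshold(n_tests)
    return EnrichmentResult(
        cell_type=cell_type,
        element_kind=element_kind,
        observed=int(observed),
        null_counts=null_counts,
        p_empirical=float(p),
        significant=p <= thr,
        nominal=p <= NOMINAL_ALPHA,
    )


def fisher_exact_2x2(table, or_kind: str = "conditional") -> FisherResult:
    """Two-sided Fisher's exact test on a 2x2 table.

    The p-value is the exact hypergeometric two-sided p (sum of the
    probabilities of all tables with the observed margins that are no
    more probable than the observed one).  The odds ratio is the
    conditional maximum-likelihood estimate by default;
    ``or_kind="sample"`` gives the cross-product ratio ad/bc instead.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("table cells must be non-negative")
    if t.sum() == 0:
        raise ValueError("all-zero table")
    p = float(_scipy_fisher(t).pvalue)
    if or_kind == "conditional":
        oddsr = float(_scipy_odds_ratio(t, kind="conditional").statistic)
    elif or_kind == "sample":
        a, b, c, d = t.ravel()
        oddsr = float(a * d) / (b * c) if b * c > 0 else np.inf
    else:
        raise ValueError("or_kind must be 'conditional' or 'sample'")
    return FisherResult(table=t, odds_ratio=oddsr, p_two_sided=p)


def variant_category_membership(
    variants: pd.DataFrame, element_categories: pd.DataFrame
) -> pd.DataFrame:
    """Boolean membership matrix: variant x sub-structure category.

    A variant is a member of a category when it overlaps >= 1 element
    carrying that category label; one variant can belong to several
    categories (it is counted once per category membership).
    """
    member = {}
    for cat in SUBSTRUCTURES:
        sub = element_categories[element_categories["category"] == cat]
        member[cat] = (
            overlaps_any(variants, sub) if len(sub) else np.zeros(len(variants), bool)
        )
    return pd.DataFrame(member)


def substructure_variant_fisher(
    networks: list[EPINetwork],
    case: pd.DataFrame,
    control: pd.DataFrame,
    category: str,
    element_kind: str = "enhancer",
    genes: pd.DataFrame | None = None,
    or_kind: str = "conditional",
) -> FisherResult:
    """Case-vs-control contrast of variant membership in one
    sub-structure category against all other categories.

    Rows are variant label (case, control); columns split the variants
    that overlap labeled elements into members of ``category`` vs
    variants whose memberships are all in other categories (so each
    overlapping variant contributes to exactly one column of its row,
    keeping the two columns independent).  Variants overlapping no
    labeled element are excluded.  Across the per-category tests a
    variant is counted once per category membership.
    """
    if category not in SUBSTRUCTURES:
        raise ValueError(f"category must be one of {SUBSTRUCTURES}")
    elements = substructure_elements(networks, element_kind=element_kind, genes=genes)
    if not (elements["category"] == category).any():
        raise ValueError(f"category {category} absent from the networks")
    table = np.zeros((2, 2), dtype=np.int64)
    others = [c for c in SUBSTRUCTURES if c != category]
    for row, variants in enumerate((case, control)):
        member = variant_category_membership(variants, elements)
        in_cat = member[category].to_numpy()
        in_other = member[others].any(axis=1).to_numpy()
        table[row, 0] = int(in_cat.sum())
        table[row, 1] = int((in_other & ~in_cat).sum())
    if table.sum() == 0:
        raise ValueError("no variant overlaps any labeled element (empty table)")
    return fisher_exact_2x2(table, or_kind=or_kind)


def build_lfc_contingency(
    de_table: pd.DataFrame,
    network_a_genes,
    network_b_genes,
    direction: str,
    comparison: str = "between",
) -> np.ndarray:
    """2x2 table of differential-expression direction vs network membership.

    ``de_table`` needs columns gene, lfc, fdr.  Genes are first filtered
    to FDR < 0.05 (strict).  The direction column splits genes passing
    the strict threshold (``up``: LFC > 1; ``down``: LFC < -1) from the
    rest.  Rows are membership in network A's target genes vs network
    B's (``comparison="between"``; genes in both contribute to both
    rows) or in-network vs out-of-network A (``comparison="within"``).
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    if comparison not in ("between", "within"):
        raise ValueError("comparison must be 'between' or 'within'")
    kept = de_table[de_table["fdr"] < 0.05]
    if kept.empty:
        raise ValueError("no gene passes the FDR < 0.05 filter")
    passes = kept["lfc"] > 1 if direction == "up" else kept["lfc"] < -1
    a = kept["gene"].isin(set(network_a_genes))
    if comparison == "between":
        b = kept["gene"].isin(set(network_b_genes))
        table = np.array(
            [
                [int((a & passes).sum()), int((a & ~passes).sum())],
                [int((b & passes).sum()), int((b & ~passes).sum())],
            ]
        )
    else:
        table = np.array(
            [
                [int((a & passes).sum()), int((a & ~passes).sum())],
                [int((~a & passes).sum()), int((~a & ~passes).sum())],
            ]
        )
    return table
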