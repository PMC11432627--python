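# Methods

## Coordinates and element identity

All coordinates are 0-based half-open (BED convention); overlap means
≥ 1 shared base, so book-ended intervals (`[100,600)` / `[600,700)`) do
not overlap. Enhancer identity within a cell type is the exact
(chrom, start, end) triple — required for unambiguous joining of TFBS
tables onto network enhancers. Promoter identity is the target-gene
symbol wherever networks are compared by gene (degree computation,
promoter uniqueness, gene-list tests, always exact full-symbol
matching); a coordinate representation — the 2000 bp upstream of the
TSS, strand-aware (`[start−2000, start)` on +, `[end, end+2000)` on −,
clipped to chromosome bounds with a warning) — is derived only where
variants must be intersected with promoters.

## ABC scoring

Activity is the geometric mean of the ATAC and H3K27ac read counts of
the 500-bp candidate element (arithmetic mean and product are available
behind the `activity_mode` switch; only ratios of activities matter, so
any non-negative count scale is acceptable). Contact is the power-law
estimate `C(d) = max(d, d_min)^(−γ)` with defaults γ = 1.0 and
d_min = 5000 bp; distance is measured from the enhancer midpoint to the
TSS position (for 500-bp elements the midpoint-vs-edge difference is
negligible and the midpoint is unambiguous). Scores are normalized per
promoter over the enhancers within 5 Mb; enhancers beyond the window
enter neither numerator nor denominator, so the in-window scores sum
to 1 and rescaling every contact (or activity) by a constant cancels
exactly. A promoter whose candidate enhancers all have zero activity is
degenerate: scores are defined as 0 with a warning rather than NaN.
Filters: keep `ABC ≥ 0.02` (scores below the threshold are removed) and
target expression strictly `> 1` TPM.

## Networks and classifications

The collapsed network is the plain concatenation of the six filtered
per-cell-type tables — duplicates across cell types are deliberately
kept — with a separately maintained enhancer list merged wherever
regions overlap by ≥ 1 bp. The subset network clusters enhancer regions
lying within 100 bp of each other (transitively; cluster interval =
union span) and collects, per cluster × target gene, the six
per-cell-type ABC scores, each the **maximum** over member records
(maximum preserves "non-zero in cell type X"; mean is available).
Classification order matters and is deliberate: (1) non-zero in ≥ 5 of
6 cell types → Ubi; (2) exactly one cell type → that cell type;
(3) ≥ 2 cell types all progenitor → Progenitor; (4) all mature →
Mature; (5) the remaining 2–4-cell-type mixed-stage EPIs are removed.
The ubiquitous rule must precede mixed-stage removal because 5 of 6
cell types necessarily spans both stages. Scores here are post-filter
scores; absent cell types contribute zero.

Sub-structures are labeled per EPI from within-network degrees:
deg(e) = distinct target genes of the enhancer, deg(g) = distinct
enhancers of the gene; C1 = (1,1), C2 = (>1,1), C3 = (1,>1),
C4 = (>1,>1). For the subset network each category group is treated as
its own EPI set when labeling (that separation is what produces the
collapsed→subset shift toward C1/C2). Per-enhancer labeling was not
implemented, only per-EPI.

## Element comparison

Enhancer uniqueness is evaluated pre-merge against the other cell
types' original intervals (zero ≥ 1-bp overlaps in all five); promoter
uniqueness by gene symbol. The enhancer Jaccard between two interval
sets is computed on union clusters: merge A∪B at ≥ 1 bp overlap into
clusters U, count clusters containing A elements (a), B elements (b)
and both (i), J = i/(a+b−i). Raw pair counting is asymmetric when set
sizes differ, which is why the union-cluster definition is the default;
a base-pair Jaccard (shared bp / union bp) is available via
`mode="basepair"`. Promoter Jaccard is the plain set Jaccard on gene
symbols. Empty-vs-empty comparisons are reported as NaN.

## TF presence

FIMO output is filtered to p strictly < 10⁻⁵, then motifs are collapsed
to TFs (the TF symbol comes from `motif_alt_id`, falling back to the
`motif_id` prefix), keeping one row per TF × enhancer with the smallest
p. The counts matrix gives the number of a cell type's network
enhancers carrying ≥ 1 site for the TF; weights divide each TF row by
its total so rows sum to 1. Note the normalization is per TF (row),
not per cell type. Clustering is Euclidean k-means, k = 3, 10
restarts, fixed seed, best inertia; clusters are named by the gap
between mean progenitor-column and mean mature-column centre weights
(largest → higher_progenitor, smallest → higher_mature, middle →
equal), ties broken by cluster index. Expression grouping assigns each
TF to its argmax-TPM cell type with ties broken by the fixed cell-type
order and flagged.

## Variant enrichment

The empirical test compares the number of a cell type's elements
carrying ≥ 1 variant (each element counted once, however many variants
it holds) with R = 1000 size-matched draws, uniform **without
replacement**, from the deduplicated pooled-network element set
(enhancers by exact interval, genes by symbol). The p-value is the
add-one upper-tail estimator `p = (1 + #{null ≥ obs})/(R + 1)` — it
never returns 0 and is consistent with "small p = enrichment"; the
plain ratio `#{null ≥ obs}/R` is available as `legacy_p`. Significance
uses 0.05/6 = 0.008333 (rounded to six decimals) for the six
per-cell-type tests and 0.05 for nominal calls.

Fisher's exact test (two-sided hypergeometric p, conditional-ML odds
ratio; cross-product ratio optional) backs the 2×2 contrasts. For the
per-sub-structure case/control contrast, a variant is attributed to
every category whose elements it overlaps, one 2×2 per category; within
a single category's table the columns are "member of the category" vs
"member only of other categories", so each element-overlapping variant
falls in exactly one column. Letting dual-membership variants count in
both columns was rejected: it correlates the columns and makes the
Fisher test markedly conservative (measured type-I ≈ 0.025 instead of
≈ 0.05). Variants overlapping no labeled element are excluded.

The differential-expression contrast filters genes to FDR strictly
< 0.05, splits them at LFC > 1 (up) or < −1 (down), and crosses that
with membership in network A's vs network B's target genes (a gene in
both networks contributes to both rows) or in-vs-out of one network.

## Synthetic data

The generator emulates the six-cell-type design on a small genome
(default 2 × 2 Mb). Enhancers are 500-bp elements on a 1-kb slot grid —
distinct slots can never overlap nor fall within 100 bp of each other,
so the ≥ 1-bp and 100-bp merge rules act only on deliberately shared
elements. Sharing classes are assigned by construction at exact counts:
per cell type 35% cell-type-specific, 25% stage-shared (present in all
three cell types of one stage), remainder ubiquitous — the 35% matches
the reported average uniqueness of enhancers per cell type, and shared
elements are written at identical coordinates by default (optional
≤ 100-bp jitter exercises the subset merge). Each enhancer links to 1–2
genes within 5 Mb on its chromosome; links are shared across the cell
types carrying the enhancer. ABC scores are drawn from a mixture with
20% of mass below the 0.02 threshold, and per-cell-type TPMs with 20%
below 1, so both filter boundaries are exercised; score and TPM
distributions are otherwise arbitrary choices for boundary coverage,
not estimates of the real networks' distributions. Scores are generated
directly so network modules are testable independently of the scoring
module; `generate_peak_counts` provides the complementary end-to-end
peak-count mode.

TFs split into three planted archetypes (progenitor-biased,
mature-biased, unbiased); a biased TF binds its own stage's enhancers
with probability p₀(1+b) and the opposite side with p₀(1−b)
(p₀ = 0.12, b = 0.6 by default). 10% of binding rows get p-values
failing the 10⁻⁵ filter and 10% of bound pairs emit a second motif row,
exercising both the filter and motif collapsing. Biased TF genes are
also expressed ~(1+2b)-fold higher in their own stage so the expression
grouping can recover the archetype.

Variants are single-base (de novo SNVs dominate the emulated variant
sets). Controls are uniform over the genome; with a planted category
(default C3 at odds 3) each case variant lands inside a target element
with probability `mf/(1−f+mf)` (f = genomic fraction covered by the
target elements) and uniformly outside them otherwise, so the planted
in-target odds are exactly m× uniform. The ground-truth manifest
records every planted signal (sharing class per enhancer, archetype per
TF, planted flag per variant, DE direction per gene, disease-list
origin per gene).

What the generator does **not** emulate: sequence content (no FASTA, no
motif PWMs), read-level noise, Hi-C matrices, correlated peak strengths
between assays, realistic gene density or LD structure between
variants. Passing recovery tests therefore shows the statistics behave
correctly under the stated sampling model, not that the pipeline's
biological conclusions transfer to any real dataset.

## Problem sizes and numerical choices

Default synthetic conditions: 300 enhancers/cell type, 200 genes,
60 TFs, 5000 case + 5000 control variants. The sharing-recovery
analysis runs at 5000 enhancers/cell type on a 4 × 5 Mb genome; power
and calibration of the sub-structure contrast use 100 planted and 1000
null replicates at the default size. Empirical-vs-exact agreement is
checked on every pool of ≤ 12 elements at R = 10⁴ (sampling error
≤ ~0.005, so the 0.01 agreement band holds with margin); Fisher
p-values are checked against exact integer enumeration on every 2×2
table with total ≤ 40. ABC normalization is verified to 10⁻⁹ (measured
error ~10⁻¹⁶); contact-scale invariance is asserted bitwise on
power-of-two distances, where the rescaling is exactly representable.
Degenerate inputs handled explicitly: all-zero-activity promoters
(scores 0 + warning), empty variant/target sets (informative errors),
all-zero Fisher tables (error), TFs with zero total binding (excluded
with warning), promoters clipped empty at chromosome edges (dropped
with warning), near-uniform TF profiles (k-means still partitions;
labeling falls back to the deterministic gap ordering).

## Known limitations

Interval operations assume a shared chromosome namespace (no alias or
genome-build handling, no LiftOver). The subset network's score
aggregation discards member multiplicity. The empirical test's pool is
the concatenated collapsed network only — no genomic-background or
GC-matched null. The per-category Fisher contrast treats variants as
exchangeable units, ignoring mutation-rate heterogeneity along the
genome. The k = 3 stage labeling presumes the three archetypes exist;
on profiles without stage structure the labels are arbitrary (though
deterministic).
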