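# epinet

Analysis of **enhancer–promoter interaction (EPI) networks** across six
neural cell types — three progenitor stages (embryonic stem cells ESC,
neural stem cells NSC, neural progenitor cells NPC) and three mature
neuron types (inhibitory AD, excitatory Ngn2, motor neurons) — and of
how disease-associated non-coding variants distribute over those
networks. It is aimed at regulatory-genomics analysts who want the
network-level statistics (element sharing, sub-structure classes,
TF presence, variant enrichment) without re-running raw read
processing: inputs are peak tables, TSS annotations, TPM tables,
FIMO-style TFBS tables and variant BEDs.

## The model

An enhancer *e* is scored against a promoter *p* with a simplified
**Activity-by-Contact (ABC)** score

```
ABC(e, p) = A(e) · C(e, p) / Σ_{e' within 5 Mb of p} A(e') · C(e', p)
```

where activity `A = √(ATAC · H3K27ac)` is the geometric mean of the
read counts over the 500-bp candidate element and contact
`C(d) = max(d, d_min)^(−γ)` is a power-law decay of genomic distance
(default γ = 1, d_min = 5 kb). Predicted interactions are kept when
`ABC ≥ 0.02` and the target gene is expressed above 1 TPM.

Downstream analyses:

* **collapsed network** — the six per-cell-type networks concatenated
  (duplicates kept) with a separately maintained ≥ 1-bp-overlap-merged
  enhancer list; **subset network** — enhancers clustered within
  100 bp and each merged EPI classified into nine categories (six
  cell-type-specific, Progenitor, Mature, ubiquitous "Ubi";
  mixed-stage EPIs removed);
* **sub-structures** — each EPI labeled C1 (single enhancer, single
  promoter), C2 (single enhancer, multiple promoters), C3 (multiple
  enhancers, single promoter) or C4 (multiple/multiple) from the
  bipartite degrees;
* **element comparison** — per-cell-type uniqueness fractions and
  6×6 Jaccard matrices for enhancers (interval overlap) and promoters
  (gene symbols);
* **TF presence** — counts of bound enhancers per TF per cell type from
  collapsed FIMO hits (p < 10⁻⁵), row-normalized to weights summing
  to 1, k-means (k = 3) into higher-progenitor / higher-mature / equal
  groups;
* **variant enrichment** — an empirical resampling test
  (`p = (1 + #{null ≥ obs}) / (R + 1)` over R = 1000 size-matched draws
  without replacement from the pooled network; corrected threshold
  0.05/6 = 0.008333) plus exact Fisher contrasts of case vs control
  variants per sub-structure category.

A fully seeded synthetic-data module generates every input with known
ground truth (sharing fractions, TF stage bias, planted variant
enrichment), so each analysis can be scored on parameter recovery.

## Worked example

```
python analysis/01_simulate.py          # write synthetic inputs
python analysis/03_build_networks.py    # collapsed + subset networks
python analysis/04_compare_elements.py  # uniqueness + Jaccard
python analysis/06_variant_enrichment.py
```

`04_compare_elements.py` prints (seed 7, default conditions):

```
mean unique enhancers: 36.7% (vs 35% planted before filtering); promoters: 0.7%
enhancer Jaccard within stages 0.339 vs across stages 0.192
```

i.e. the planted 35% cell-type-specific enhancer fraction is recovered
after filtering, promoters are almost entirely shared, and element
overlap is highest between cell types of the same differentiation
stage. `06_variant_enrichment.py` prints the per-category Fisher
contrasts; with a 3× case enrichment planted in C3 elements:

```
category  case_in  case_other  control_in  control_other  odds_ratio      p
      C3      642         112         348            123      2.0248 0.0000
```

the planted category is flagged (OR ≈ 2, p ≈ 10⁻⁹ scale) while the
control variants stay at background. `03_build_networks.py` shows the
collapsed→subset sub-structure shift (C1+C2 share 0.158 → 0.526 once
cross-cell-type duplicate EPIs are separated).

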