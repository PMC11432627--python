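"""Promoter derivation, empirical resampling test, Fisher contrasts."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom, kstest

from epinet.network_builder import EPINetwork
from epinet.variant_enrichment import (
    build_lfc_contingency,
    corrected_threshold,
    count_elements_with_variant,
    derive_promoter_regions,
    empirical_enrichment_test,
    fisher_exact_2x2,
    substructure_variant_fisher,
)


def intervals(*triples):
    return pd.DataFrame(triples, columns=["chrom", "start", "end"])


def point_variants(*positions, chrom="chr1"):
    return pd.DataFrame(
        {"chrom": chrom, "start": list(positions), "end": [p + 1 for p in positions]}
    )


def fisher_enumeration_oracle(table):
    """Exact two-sided Fisher p by rational enumeration of all tables
    with the observed margins (a table counts when its hypergeometric
    probability is <= the observed table's, compared exactly)."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    w_obs = comb(r1, a) * comb(r2, c1 - a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    total = comb(n, c1)
    kept = sum(
        comb(r1, x) * comb(r2, c1 - x)
        for x in range(lo, hi + 1)
        if comb(r1, x) * comb(r2, c1 - x) <= w_obs
    )
    return Fraction(kept, total)


class TestCorrectedThreshold:
    def test_six_tests(self):
        assert corrected_threshold(6) == 0.008333

    def test_invalid(self):
        with pytest.raises(ValueError):
            corrected_threshold(0)


class TestPromoterRegions:
    def genes(self, rows):
        return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end", "strand"])

    def test_plus_strand_upstream(self):
        out = derive_promoter_regions(self.genes([("G", "chr1", 10_000, 15_000, "+")]))
        assert out[["start", "end"]].values.tolist() == [[8000, 10_000]]

    def test_minus_strand_downstream_of_end(self):
        out = derive_promoter_regions(self.genes([("G", "chr1", 15_000, 20_000, "-")]))
        assert out[["start", "end"]].values.tolist() == [[20_000, 22_000]]

    def test_clip_at_chromosome_start(self):
        with pytest.warns(UserWarning, match="clipped"):
            out = derive_promoter_regions(self.genes([("G", "chr1", 1500, 9000, "+")]))
        assert out[["start", "end"]].values.tolist() == [[0, 1500]]

    def test_unknown_strand_rejected(self):
        with pytest.raises(ValueError, match="strand"):
            derive_promoter_regions(self.genes([("G", "chr1", 1500, 9000, ".")]))


class TestVariantCounting:
    def test_element_counted_once(self):
        elements = intervals(("chr1", 100, 600))
        assert count_elements_with_variant(elements, point_variants(110, 120, 130, 140, 150)) == 1

    def test_no_overlap(self):
        assert count_elements_with_variant(intervals(("chr1", 100, 600)), point_variants(700)) == 0

    def test_bruteforce_small_case(self):
        elements = intervals(("chr1", 0, 100), ("chr1", 200, 300), ("chr1", 400, 500))
        variants = point_variants(50, 250, 260, 350)
        # per-element scan: elements 1 and 2 carry variants, element 3 none
        expected = sum(
            any(s <= v < e for v in [50, 250, 260, 350])
            for s, e in [(0, 100), (200, 300), (400, 500)]
        )
        assert count_elements_with_variant(elements, variants) == expected == 2


class TestEmpiricalTest:
    def pool5(self):
        pool = intervals(*[("chr1", i * 1000, i * 1000 + 100) for i in range(5)])
        variants = point_variants(50, 1050)  # elements 0 and 1 bear variants
        return pool, variants

    def test_target_equals_pool_gives_p_one(self):
        pool, variants = self.pool5()
        res = empirical_enrichment_test(pool, pool, variants, "enhancer", reps=200, seed=0)
        assert res.p_empirical == pytest.approx(1.0)

    def test_matches_hypergeometric_oracle(self):
        pool, variants = self.pool5()
        target = pool.iloc[:2]  # exactly the two bearing elements
        res = empirical_enrichment_test(target, pool, variants, "enhancer", reps=10_000, seed=1)
        # exact tail P(X >= 2) with N=5, K=2, k=2 is 1/C(5,2) = 0.1
        assert res.observed == 2
        assert abs(res.p_empirical - 0.1) <= 0.01

    def test_significance_flags(self):
        pool, variants = self.pool5()
        # p ~ 0.1: neither significant nor nominal
        weak = empirical_enrichment_test(pool.iloc[:2], pool, variants, "enhancer", reps=10_000, seed=1)
        assert not weak.significant and not weak.nominal
        # pool of 30 with the 2 bearing elements as target:
        # exact tail 1/C(30,2) ~ 0.0023 <= 0.008333 -> significant
        big_pool = intervals(*[("chr1", i * 1000, i * 1000 + 100) for i in range(30)])
        strong = empirical_enrichment_test(
            big_pool.iloc[:2], big_pool, variants, "enhancer", reps=10_000, seed=1
        )
        assert strong.significant and strong.nominal

    def test_seeded_reproducibility(self):
        pool, variants = self.pool5()
        a = empirical_enrichment_test(pool.iloc[:2], pool, variants, "enhancer", reps=500, seed=9)
        b = empirical_enrichment_test(pool.iloc[:2], pool, variants, "enhancer", reps=500, seed=9)
        assert np.array_equal(a.null_counts, b.null_counts)
        assert a.p_empirical == b.p_empirical

    def test_target_larger_than_pool_errors(self):
        pool, variants = self.pool5()
        with pytest.raises(ValueError, match="pool"):
            empirical_enrichment_test(pool, pool.iloc[:2], variants, "enhancer")

    def test_empty_variants_error(self):
        pool, _ = self.pool5()
        with pytest.raises(ValueError, match="empty variant set"):
            empirical_enrichment_test(pool.iloc[:2], pool, point_variants(), "enhancer")

    def test_gene_kind_exact_matching(self):
        res = empirical_enrichment_test(
            ["SOX2", "POU5F1"],
            ["SOX2", "POU5F1", "A", "B", "C"],
            {"SOX21", "POU5F1"},  # SOX2 must not match SOX21
            "gene",
            reps=2000,
            seed=0,
        )
        assert res.observed == 1

    def test_legacy_p_formula(self):
        pool, variants = self.pool5()
        res = empirical_enrichment_test(
            pool.iloc[:2], pool, variants, "enhancer", reps=1000, seed=2, legacy_p=True
        )
        n_ge = int((res.null_counts >= res.observed).sum())
        assert res.p_empirical == n_ge / 1000

    def test_monotone_in_observed(self):
        """p is non-increasing in the observed count for a fixed null."""
        pool, variants = self.pool5()
        res = empirical_enrichment_test(pool.iloc[:2], pool, variants, "enhancer", reps=2000, seed=3)
        null = res.null_counts
        ps = [(1 + (null >= o).sum()) / 2001 for o in range(0, 3)]
        assert ps == sorted(ps, reverse=True)

    def test_null_p_values_are_uniform(self):
        """Calibration: with unplanted variants the empirical p over many
        replicates is approximately uniform (KS distance < 0.08)."""
        rng = np.random.default_rng(12)
        n_pool, k = 600, 300
        pool = intervals(*[("chr1", i * 1000, i * 1000 + 300) for i in range(n_pool)])
        ps = []
        for r in range(500):
            variants = point_variants(*rng.integers(0, n_pool * 1000, size=1200))
            target = pool.iloc[np.sort(rng.choice(n_pool, size=k, replace=False))]
            res = empirical_enrichment_test(
                target, pool, variants, "enhancer", reps=1000, seed=int(r)
            )
            ps.append(res.p_empirical)
        dist = kstest(ps, "uniform").statistic
        assert dist < 0.08


class TestFisher:
    def test_balanced_table(self):
        res = fisher_exact_2x2([[5, 5], [5, 5]])
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_two_sided == pytest.approx(1.0)

    def test_diagonal_2_2(self):
        res = fisher_exact_2x2([[2, 0], [0, 2]])
        assert res.p_two_sided == pytest.approx(1 / 3)

    def test_diagonal_10_10(self):
        res = fisher_exact_2x2([[10, 0], [0, 10]])
        assert res.p_two_sided == pytest.approx(2 / comb(20, 10))

    def test_matches_enumeration_oracle_on_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(300):
            t = rng.integers(0, 15, size=(2, 2))
            if t.sum() == 0:
                continue
            res = fisher_exact_2x2(t)
            assert res.p_two_sided == pytest.approx(
                float(fisher_enumeration_oracle(t)), rel=1e-9, abs=1e-12
            )

    def test_sample_odds_ratio_option(self):
        res = fisher_exact_2x2([[10, 5], [2, 8]], or_kind="sample")
        assert res.odds_ratio == pytest.approx(10 * 8 / (5 * 2))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            fisher_exact_2x2([[0, 0], [0, 0]])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [0, 2]])


class TestSubstructureFisher:
    def nets(self):
        records = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": [1000, 1000, 5000, 9000],
                "end": [1500, 1500, 5500, 9500],
                "cell_type": "ESC",
                "target_gene": ["G1", "G2", "G1", "G3"],
                "tss": 100_000,
                "gene_strand": "+",
                "abc_score": 0.1,
                "target_tpm": 2.0,
            }
        )
        return [EPINetwork(records, "ESC")]

    def test_no_variant_in_elements_errors(self):
        with pytest.raises(ValueError, match="empty table"):
            substructure_variant_fisher(
                self.nets(), point_variants(50_000), point_variants(60_000), "C4"
            )

    def test_absent_category_errors(self):
        # a single lone-pair network only contains C1 elements
        lone = EPINetwork(self.nets()[0].records.iloc[[3]].reset_index(drop=True), "ESC")
        with pytest.raises(ValueError, match="absent"):
            substructure_variant_fisher(
                [lone], point_variants(9100), point_variants(9200), "C4"
            )

    def test_counts_by_category_membership(self):
        # E@1000 edges: C4 (G1) and C2 (G2); E@5000: C3; E@9000: C1
        case = point_variants(1100, 5100)  # one in {C4,C2} element, one in C3
        control = point_variants(9100)  # in the C1 element
        res = substructure_variant_fisher(self.nets(), case, control, "C3")
        assert res.table.tolist() == [[1, 1], [0, 1]]


class TestLfcContingency:
    def de(self):
        return pd.DataFrame(
            {
                "gene": ["A", "B", "C", "D", "E"],
                "lfc": [2.0, 1.0, -2.0, 0.5, 3.0],
                "fdr": [0.01, 0.01, 0.02, 0.03, 0.05],
            }
        )

    def test_strict_boundaries(self):
        # E has FDR exactly 0.05 -> excluded; B has LFC exactly 1 -> not "up"
        table = build_lfc_contingency(self.de(), {"A", "B", "E"}, {"C", "D"}, "up")
        assert table.tolist() == [[1, 1], [0, 2]]

    def test_down_direction(self):
        table = build_lfc_contingency(self.de(), {"C"}, {"A"}, "down")
        assert table.tolist() == [[1, 0], [0, 1]]

    def test_within_network_comparison(self):
        table = build_lfc_contingency(self.de(), {"A"}, set(), "up", comparison="within")
        assert table.tolist() == [[1, 0], [0, 3]]

    def test_empty_after_filter_errors(self):
        de = self.de().assign(fdr=0.9)
        with pytest.raises(ValueError, match="FDR"):
            build_lfc_contingency(de, {"A"}, {"B"}, "up")

    def test_planted_de_recovery(self, small_config, small_dataset):
        from epinet.synthetic_data import generate_expression_and_genesets

        bundle = generate_expression_and_genesets(small_config, small_dataset)
        npc = set(small_dataset.epi_tables["NPC"]["target_gene"])
        esc = set(small_dataset.epi_tables["ESC"]["target_gene"])
        table = build_lfc_contingency(bundle.de_table, npc, esc, "up")
        res = fisher_exact_2x2(table)
        assert res.odds_ratio > 1
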