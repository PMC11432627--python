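"""The synthetic-study generator: determinism, planted structure, manifest."""

import numpy as np
import pandas as pd
import pytest

from epinet.abc_scoring import filter_epis
from epinet.intervals import overlaps_any
from epinet.io_formats import collapse_fimo_frame, read_epi_table, read_tpm_table
from epinet.network_builder import EPINetwork, substructure_elements
from epinet.synthetic_data import (
    SyntheticConfig,
    generate_epi_tables,
    generate_expression_and_genesets,
    generate_genome,
    generate_tfbs_table,
    generate_variant_sets,
    write_dataset,
)


def dataset_for(**kw):
    cfg = SyntheticConfig(**kw)
    return cfg, generate_epi_tables(cfg, generate_genome(cfg))


class TestConfigValidation:
    def test_zero_chrom_length_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(chrom_length=0)

    def test_infeasible_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            SyntheticConfig(frac_celltype_specific_enh=0.7, frac_stage_shared_enh=0.5)

    def test_planted_odds_below_one_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(planted_odds=0.5)

    def test_yaml_roundtrip(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("seed: 5\nn_genes: 50\nfrac_stage_shared_enh: 0.1\n")
        cfg = SyntheticConfig.from_yaml(p)
        assert (cfg.seed, cfg.n_genes, cfg.frac_stage_shared_enh) == (5, 50, 0.1)


class TestGenome:
    def test_echoes_config(self):
        cfg = SyntheticConfig(seed=1, n_chromosomes=2, chrom_length=1_000_000)
        g = generate_genome(cfg)
        assert g["chrom"].tolist() == ["chr1", "chr2"]
        assert g["length"].tolist() == [1_000_000] * 2

    def test_deterministic(self):
        cfg = SyntheticConfig(seed=1)
        assert generate_genome(cfg).equals(generate_genome(cfg))


class TestDeterminism:
    def test_identical_seed_identical_outputs(self):
        _, a = dataset_for(seed=21, n_enhancers_per_celltype=100, n_genes=60)
        _, b = dataset_for(seed=21, n_enhancers_per_celltype=100, n_genes=60)
        for ct in a.epi_tables:
            pd.testing.assert_frame_equal(a.epi_tables[ct], b.epi_tables[ct])
        pd.testing.assert_frame_equal(a.enhancers, b.enhancers)

    def test_different_seed_differs(self):
        _, a = dataset_for(seed=21, n_enhancers_per_celltype=100, n_genes=60)
        _, b = dataset_for(seed=22, n_enhancers_per_celltype=100, n_genes=60)
        assert not a.epi_tables["ESC"].equals(b.epi_tables["ESC"])

    def test_byte_identical_files(self, tmp_path):
        for sub in ("x", "y"):
            cfg = SyntheticConfig(seed=8, n_enhancers_per_celltype=80, n_genes=50)
            ds = generate_epi_tables(cfg, generate_genome(cfg))
            fimo = generate_tfbs_table(cfg, ds)
            bundle = generate_expression_and_genesets(cfg, ds)
            case, control = generate_variant_sets(cfg, ds)
            write_dataset(ds, tmp_path / sub, bundle=bundle, fimo=fimo, case=case, control=control)
        for f in (tmp_path / "x").iterdir():
            assert f.read_bytes() == (tmp_path / "y" / f.name).read_bytes(), f.name


class TestSharingStructure:
    def test_fully_specific_never_overlaps_other_cell_types(self):
        _, ds = dataset_for(
            seed=2, frac_celltype_specific_enh=1.0, frac_stage_shared_enh=0.0,
            n_enhancers_per_celltype=100, n_genes=60,
        )
        nets = {ct: t[["chrom", "start", "end"]].drop_duplicates() for ct, t in ds.epi_tables.items()}
        for ct, enh in nets.items():
            others = pd.concat([e for c, e in nets.items() if c != ct], ignore_index=True)
            assert not overlaps_any(enh, others).any()

    def test_manifest_fractions_match_generated_data_exactly(self):
        cfg, ds = dataset_for(seed=3, n_enhancers_per_celltype=200, n_genes=80)
        counts = ds.enhancers["sharing_class"].value_counts()
        n_spec_per_ct = counts.get("cell_type_specific", 0) / 6
        n_stage_per_stage = counts.get("stage_shared", 0) / 2
        n_ubi = counts.get("ubiquitous", 0)
        per_ct_total = n_spec_per_ct + n_stage_per_stage + n_ubi
        assert per_ct_total == cfg.n_enhancers_per_celltype
        assert ds.manifest.sharing_fractions["cell_type_specific"] == n_spec_per_ct / per_ct_total
        # every cell type's table has exactly the configured enhancer count
        for t in ds.epi_tables.values():
            assert len(t[["chrom", "start", "end"]].drop_duplicates()) == cfg.n_enhancers_per_celltype

    def test_epis_within_five_mb(self):
        _, ds = dataset_for(seed=4, n_enhancers_per_celltype=100, n_genes=60)
        for t in ds.epi_tables.values():
            mid = (t["start"] + t["end"]) // 2
            assert ((t["tss"] - mid).abs() <= 5_000_000).all()

    def test_filter_noop_when_all_pass(self):
        _, ds = dataset_for(
            seed=5, frac_abc_below_threshold=0.0, frac_tpm_below_1=0.0,
            n_enhancers_per_celltype=100, n_genes=60,
        )
        for t in ds.epi_tables.values():
            assert len(filter_epis(t)) == len(t)


class TestTfbs:
    def test_all_weak_pvalues_filtered_out(self):
        cfg, ds = dataset_for(seed=6, n_enhancers_per_celltype=80, n_genes=50)
        cfg2 = SyntheticConfig(**{**cfg.__dict__, "frac_weak_tfbs": 1.0})
        fimo = generate_tfbs_table(cfg2, ds)
        assert collapse_fimo_frame(fimo).empty

    def test_unbiased_tfs_have_near_uniform_weights(self):
        from epinet.tf_presence import binary_presence_matrix, weighted_presence_matrix

        cfg, ds = dataset_for(seed=7, tf_stage_bias=0.0, n_enhancers_per_celltype=200, n_genes=80, n_tfs=30)
        fimo = generate_tfbs_table(cfg, ds)
        nets = [EPINetwork(t, ct) for ct, t in ds.epi_tables.items()]
        w = weighted_presence_matrix(binary_presence_matrix(collapse_fimo_frame(fimo), nets))
        assert np.allclose(w.mean(axis=0), 1 / 6, atol=0.02)

    def test_too_few_tfs_rejected(self):
        cfg, ds = dataset_for(seed=8, n_enhancers_per_celltype=80, n_genes=50)
        cfg2 = SyntheticConfig(**{**cfg.__dict__, "n_tfs": 2})
        with pytest.raises(ValueError, match="k-means"):
            generate_tfbs_table(cfg2, ds)


class TestVariants:
    def test_absent_planted_category_rejected(self):
        cfg, ds = dataset_for(
            seed=9, planted_substructure="C3", planted_odds=3.0,
            n_enhancers_per_celltype=80, n_genes=50,
        )
        empty_elems = pd.DataFrame(columns=["chrom", "start", "end", "category"])
        with pytest.raises(ValueError, match="absent"):
            generate_variant_sets(cfg, ds, empty_elems)

    def test_zero_case_variants_runs_but_enrichment_errors(self):
        cfg, ds = dataset_for(seed=10, n_case_variants=0, n_enhancers_per_celltype=80, n_genes=50)
        case, control = generate_variant_sets(cfg, ds)
        assert case.empty and len(control) == cfg.n_control_variants
        from epinet.variant_enrichment import empirical_enrichment_test

        pool = ds.epi_tables["ESC"][["chrom", "start", "end"]].drop_duplicates()
        with pytest.raises(ValueError, match="empty variant set"):
            empirical_enrichment_test(pool.iloc[:5], pool, case, "enhancer")

    def test_variants_are_single_base_and_in_bounds(self):
        cfg, ds = dataset_for(seed=11, n_enhancers_per_celltype=80, n_genes=50)
        case, control = generate_variant_sets(cfg, ds)
        for v in (case, control):
            assert ((v["end"] - v["start"]) == 1).all()
            assert (v["start"] >= 0).all()
            assert (v["end"] <= cfg.chrom_length).all()

    def test_planted_case_variants_hit_target_category(self):
        cfg, ds = dataset_for(
            seed=12, planted_substructure="C3", planted_odds=4.0,
            n_enhancers_per_celltype=150, n_genes=80,
        )
        nets = [EPINetwork(t, ct) for ct, t in ds.epi_tables.items()]
        elems = substructure_elements(nets)
        case, control = generate_variant_sets(cfg, ds, elems)
        target = elems[elems["category"] == "C3"]
        case_hits = overlaps_any(case, target).mean()
        control_hits = overlaps_any(control, target).mean()
        assert case_hits > 2 * control_hits


class TestExpressionBundle:
    def test_roundtrip_and_truth_tables(self, tmp_path, small_config, small_dataset):
        bundle = generate_expression_and_genesets(small_config, small_dataset)
        write_dataset(small_dataset, tmp_path, bundle=bundle)
        back = read_tpm_table(tmp_path / "tpm_ESC.tsv")
        assert back == bundle.tpm_tables["ESC"]
        epi = read_epi_table(tmp_path / "epi_ESC.tsv")
        pd.testing.assert_frame_equal(epi, small_dataset.epi_tables["ESC"])

    def test_disease_list_overlap_fraction(self, small_config, small_dataset):
        bundle = generate_expression_and_genesets(small_config, small_dataset)
        truth = small_dataset.manifest.disease_gene_truth
        assert len(bundle.disease_genes) == small_config.n_disease_genes
        frac = truth["from_targets"].mean()
        assert frac == pytest.approx(small_config.frac_disease_gene_overlap, abs=0.05)
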