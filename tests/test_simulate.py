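"""Synthetic genotype/annotation/phenotype generation and its calibration."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

import poda
from poda.qc import hwe_test_vector, genotype_counts, maf_vector
from poda.simulate import (
    PopulationStructure,
    SyntheticTruth,
    causal_preset,
    generate_annotation,
    generate_dataset,
    generate_genotypes,
    generate_phenotype,
    liability,
    null_preset,
    population_labels,
    write_dataset,
)


class TestGenotypes:
    def test_same_seed_identical(self):
        t1 = null_preset(42, n_samples=50, n_snps=200, n_genes=50, missing_rate=0.05)
        t2 = null_preset(42, n_samples=50, n_snps=200, n_genes=50, missing_rate=0.05)
        g1, g2 = generate_genotypes(t1), generate_genotypes(t2)
        np.testing.assert_array_equal(g1.dosage, g2.dosage)
        assert g1.samples == g2.samples

    def test_hwe_holds_without_structure(self):
        """>= 99% of SNPs pass the HWE filter threshold under the null model."""
        t = null_preset(3, n_samples=300, n_snps=2000, n_genes=500)
        g = generate_genotypes(t)
        p = hwe_test_vector(*genotype_counts(g.dosage))
        assert (p > 1e-8).mean() >= 0.99

    def test_degenerate_maf_range_concentrates(self):
        t = null_preset(4, n_samples=500, n_snps=1000, n_genes=500, maf_range=(0.3, 0.3))
        g = generate_genotypes(t)
        maf = maf_vector(g.dosage)
        se = np.sqrt(0.3 * 0.7 / (2 * 500))
        assert (np.abs(maf - 0.3) <= 3 * se).mean() >= 0.95

    def test_structure_separates_subpopulations(self):
        t = SyntheticTruth(
            seed=5, n_samples=100, n_snps=1500, n_genes=300,
            structure=PopulationStructure(fst=0.1, fraction_pop2=0.5),
        )
        g = generate_genotypes(t)
        pop = population_labels(t)
        rep = poda.pca_screen(g)
        pc1 = rep.pca_scores["PC1"].to_numpy()
        assert abs(pc1[pop == 0].mean() - pc1[pop == 1].mean()) > 3 * pc1.std() / 2

    def test_missingness_rate_applied(self):
        t = null_preset(6, n_samples=200, n_snps=500, n_genes=200, missing_rate=0.1)
        g = generate_genotypes(t)
        assert np.isnan(g.dosage).mean() == pytest.approx(0.1, abs=0.01)

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ValueError, match="maf_range"):
            SyntheticTruth(seed=0, maf_range=(0.0, 0.5))
        with pytest.raises(ValueError, match="missing_rate"):
            SyntheticTruth(seed=0, missing_rate=0.5)


class TestAnnotation:
    def test_every_gene_gets_a_snp(self):
        t = null_preset(7, n_samples=10, n_snps=330, n_genes=100, n_pathways=20)
        m, _ = generate_annotation(t)
        covered = set().union(*m.entries.values())
        assert covered == {f"GENE{i:04d}" for i in range(100)}

    def test_pathway_sizes_honor_minimum(self):
        t = null_preset(8, n_samples=10, n_snps=500, n_genes=200, n_pathways=30)
        _, db = generate_annotation(t)
        assert all(len(db[p].genes) >= 5 for p in db)

    def test_causal_pathway_holds_causal_genes(self):
        t = causal_preset(9, n_samples=10)
        m, db = generate_annotation(t)
        assert t.causal_pathway in db.pathways
        assert len(t.causal_snps) == t.n_causal
        causal_genes = {next(iter(m.entries[s])) for s in t.causal_snps}
        assert causal_genes == set(db[t.causal_pathway].genes)

    def test_same_seed_identical(self):
        t1 = null_preset(10, n_samples=10, n_snps=200, n_genes=50, n_pathways=10)
        t2 = null_preset(10, n_samples=10, n_snps=200, n_genes=50, n_pathways=10)
        _, db1 = generate_annotation(t1)
        _, db2 = generate_annotation(t2)
        assert {p: db1[p].genes for p in db1} == {p: db2[p].genes for p in db2}

    def test_infeasible_sizes_rejected(self):
        with pytest.raises(ValueError, match="round-robin"):
            SyntheticTruth(seed=0, n_snps=10, n_genes=50)


class TestPhenotypes:
    def test_null_effect_leaves_maf_balanced(self):
        """With beta = 0 the case/control dosage difference is centered on 0."""
        diffs = []
        for seed in range(8):
            t = causal_preset(seed, n_samples=400, beta_per_snp=0.0, baseline_logodds=0.0)
            t.n_snps, t.n_genes, t.n_pathways = 300, 60, 5
            ds = generate_dataset(t)
            b = poda.code_trait(ds.phenotypes, "steatohepatitis")
            included, is_case = b.mask_arrays(ds.genotypes.samples)
            idx = ds.genotypes.snp_index()
            x = ds.genotypes.dosage[:, [idx[s] for s in t.causal_snps]]
            diffs.append(x[is_case & included].mean() - x[~is_case & included].mean())
        assert abs(np.mean(diffs)) < 0.05

    def test_positive_effect_raises_case_dosage(self):
        hits = 0
        for seed in range(10):
            t = causal_preset(seed, n_samples=1000, beta_per_snp=0.5)
            t.n_snps, t.n_genes, t.n_pathways = 300, 60, 5
            ds = generate_dataset(t)
            b = poda.code_trait(ds.phenotypes, "steatohepatitis")
            included, is_case = b.mask_arrays(ds.genotypes.samples)
            idx = ds.genotypes.snp_index()
            x = ds.genotypes.dosage[:, [idx[s] for s in t.causal_snps]]
            case_mean = x[is_case & included].mean()
            ctrl_mean = x[~is_case & included].mean()
            hits += case_mean > ctrl_mean
        assert hits >= 9  # >= 95% of replicates in expectation

    def test_baseline_sets_prevalence(self):
        """logit^-1(-1.1) ~ 0.25 prevalence with no genetic effects."""
        t = null_preset(11, n_samples=4000, n_snps=100, n_genes=50, n_pathways=5,
                        pathway_size_range=(5, 20), baseline_logodds=-1.1,
                        borderline_rate=0.0)
        ds = generate_dataset(t)
        prev = (ds.phenotypes.data["steatohepatitis"] == "definite").mean()
        expected = 1 / (1 + np.exp(1.1))
        se = np.sqrt(expected * (1 - expected) / 4000)
        assert abs(prev - expected) < 4 * se

    def test_all_seven_traits_codeable(self, tiny_dataset):
        for trait in poda.TRAITS:
            b = poda.code_trait(tiny_dataset.phenotypes, trait)
            n_case, n_ctrl, _ = poda.trait_summary(b)
            assert n_case > 0 and n_ctrl > 0

    def test_liability_uses_causal_dosages(self):
        t = causal_preset(12, n_samples=50)
        t.n_snps, t.n_genes, t.n_pathways = 200, 40, 5
        generate_annotation(t)
        g = generate_genotypes(t)
        eta = liability(g, t)
        assert np.ptp(eta) > 0  # varies across samples through genotype


class TestDatasetRoundTrip:
    def test_written_files_read_back(self, tmp_path):
        t = null_preset(13, n_samples=30, n_snps=100, n_genes=30, n_pathways=6,
                        pathway_size_range=(5, 10), missing_rate=0.05)
        ds = generate_dataset(t)
        paths = write_dataset(ds, tmp_path / "d", genotype_format="tsv")
        g = poda.read_dosage_tsv(paths["dosage"])
        np.testing.assert_array_equal(g.dosage, ds.genotypes.dosage)
        m = poda.read_snp_gene_map(paths["snp_gene_map"])
        assert m.entries == ds.snp_gene_map.entries
        db = poda.read_gmt(paths["gmt"])
        assert {p: db[p].genes for p in db} == {
            p: ds.pathway_db[p].genes for p in ds.pathway_db
        }
        pheno = poda.read_phenotype_csv(paths["phenotypes"])
        assert pheno.samples == ds.phenotypes.samples
        assert paths["truth"].exists()

    def test_end_to_end_determinism(self, tmp_path):
        kw = dict(n_samples=20, n_snps=80, n_genes=20, n_pathways=5,
                  pathway_size_range=(5, 8))
        p1 = write_dataset(generate_dataset(null_preset(14, **kw)), tmp_path / "a")
        p2 = write_dataset(generate_dataset(null_preset(14, **kw)), tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()
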