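"""Distance scores, distinction scores, and the resampling null.

The brute-force oracle (explicit loops over sample pairs and leave-one-out
means) is kept independent of the production path so the vectorized engine
is checked against first principles.
"""

import itertools

import numpy as np
import pandas as pd
import pytest

import poda
from poda.core import PodaEngine, distance_scores, distinction_score, pairwise_distance, resample_pds
from poda.io import Pathway, PathwayDB, SnpGeneMap
from poda.phenotypes import BinaryTrait
from poda.universe import build_universe
from tests.conftest import random_genotypes


def brute_force_scores(x, is_case, n_snps_for_eps=None):
    """Independent S computation: explicit pairwise-complete loops."""
    n, k = x.shape
    k_eps = n_snps_for_eps if n_snps_for_eps is not None else k

    def dist(i, j):
        ok = np.isfinite(x[i]) & np.isfinite(x[j])
        return np.abs(x[i][ok] - x[j][ok]).mean() if ok.any() else np.nan

    eps = 1.0 / (2.0 * k_eps * n)
    s = np.empty(n)
    for i in range(n):
        dc = np.mean([dist(i, j) for j in range(n) if is_case[j] and j != i])
        dn = np.mean([dist(i, j) for j in range(n) if not is_case[j] and j != i])
        s[i] = np.log2(dn + eps) - np.log2(dc + eps)
    return s


def swap_labels(b: BinaryTrait) -> BinaryTrait:
    return BinaryTrait(
        b.name,
        b.labels.map({"case": "control", "control": "case", "excluded": "excluded"}),
    )


def _trait_for(g, n_cases):
    labels = {
        s: ("case" if i < n_cases else "control") for i, s in enumerate(g.samples)
    }
    return BinaryTrait("t", pd.Series(labels))


class TestPairwiseDistance:
    def test_identity(self):
        assert pairwise_distance([0, 1, 2], [0, 1, 2]) == 0.0

    def test_opposite_homozygotes(self):
        assert pairwise_distance([0, 2], [2, 0]) == 2.0

    def test_missing_pairwise_complete(self):
        assert pairwise_distance([0, 1, np.nan], [1, 1, 2]) == 0.5

    def test_no_complete_snp_is_an_error(self):
        with pytest.raises(ValueError, match="pairwise-complete"):
            pairwise_distance([np.nan, 1], [0, np.nan])

    def test_symmetric(self, rng):
        a = rng.integers(0, 3, 20).astype(float)
        b = rng.integers(0, 3, 20).astype(float)
        assert pairwise_distance(a, b) == pairwise_distance(b, a)


class TestDistanceScores:
    def test_equidistant_sample_scores_zero(self):
        # S4 is at dosage 1: distance 1 to every case (0) and control (2)
        d = np.array([[0, 0], [0, 0], [2, 2], [2, 2], [1, 1]], dtype=float)
        g = poda.GenotypeMatrix.from_dosage([f"S{i}" for i in range(5)], ["a", "b"], d)
        b = _trait_for(g, 2)
        res = distance_scores(g, ["a", "b"], b)
        assert res.s[4] == pytest.approx(0.0, abs=1e-12)

    def test_worked_six_sample_fixture(self):
        """3 cases all dosage-2 at 2 SNPs, 3 controls all dosage-0.

        Within-class distances are 0 and cross-class distances 2, so with
        eps = 1/(2*2*6) every case has S = log2(2 + eps) - log2(eps)
        = log2(49) and every control the negative; DS = 2*log2(49).
        """
        d = np.array([[2, 2]] * 3 + [[0, 0]] * 3, dtype=float)
        g = poda.GenotypeMatrix.from_dosage([f"S{i}" for i in range(6)], ["a", "b"], d)
        b = _trait_for(g, 3)
        res = distance_scores(g, ["a", "b"], b)
        np.testing.assert_allclose(res.s, brute_force_scores(d, res.is_case))
        expected = np.log2(49.0)
        np.testing.assert_allclose(res.s[:3], expected)
        np.testing.assert_allclose(res.s[3:], -expected)
        assert distinction_score(res) == pytest.approx(2 * expected)

    def test_matches_brute_force_with_missing(self, rng):
        g = random_genotypes(rng, 25, 8, missing_rate=0.15)
        b = _trait_for(g, 10)
        res = distance_scores(g, g.snp_ids, b)
        expected = brute_force_scores(g.dosage, res.is_case)
        np.testing.assert_allclose(res.s, expected, atol=1e-12)

    def test_label_swap_negates_scores_bitwise(self, rng):
        g = random_genotypes(rng, 20, 6)
        b = _trait_for(g, 8)
        s1 = distance_scores(g, g.snp_ids, b).s
        s2 = distance_scores(g, g.snp_ids, swap_labels(b)).s
        assert np.array_equal(s1, -s2)

    def test_needs_two_per_class(self, rng):
        g = random_genotypes(rng, 5, 4)
        with pytest.raises(ValueError, match=">=2"):
            distance_scores(g, g.snp_ids, _trait_for(g, 1))

    def test_sample_without_complete_pairs_excluded_with_warning(self, rng):
        g = random_genotypes(rng, 10, 4)
        d = g.dosage.copy()
        d[0] = np.nan  # S0 has no genotype at any pathway SNP
        g2 = poda.GenotypeMatrix.from_dosage(g.samples, g.snp_ids, d)
        with pytest.warns(UserWarning, match="undefined"):
            res = distance_scores(g2, g.snp_ids, _trait_for(g, 4))
        assert "S0" not in res.samples
        assert len(res.samples) == 9


class TestDistinctionScore:
    def test_constant_scores_give_zero(self):
        d = poda.DistanceScoreSet(None, "t", ["a", "b", "c", "d"],
                                  np.ones(4), np.array([True, True, False, False]), ["x"])
        assert distinction_score(d) == 0.0

    def test_label_swap_on_fixed_scores_negates_bitwise(self, rng):
        s = rng.normal(size=30)
        is_case = rng.random(30) < 0.4
        if not is_case.any() or is_case.all():
            is_case[:3], is_case[3:] = True, False
        d1 = poda.DistanceScoreSet(None, "t", [str(i) for i in range(30)], s, is_case, ["x"])
        d2 = poda.DistanceScoreSet(None, "t", d1.samples, s, ~is_case, ["x"])
        assert distinction_score(d1) == -distinction_score(d2)

    def test_single_class_rejected(self):
        d = poda.DistanceScoreSet(None, "t", ["a"], np.zeros(1), np.array([True]), ["x"])
        with pytest.raises(ValueError):
            distinction_score(d)


def tiny_world(rng, n_samples=30, n_genes=6, snps_per_gene=2, pathway_genes=3):
    """A universe small enough to enumerate every same-size gene set."""
    n_snps = n_genes * snps_per_gene
    g = random_genotypes(rng, n_samples, n_snps)
    entries = {
        g.snp_ids[i]: {f"G{i % n_genes}"} for i in range(n_snps)
    }
    m = SnpGeneMap(entries)
    genes = [f"G{i}" for i in range(n_genes)]
    db = PathwayDB(
        {
            "target": Pathway("target", "s", frozenset(genes[:pathway_genes])),
            "rest": Pathway("rest", "s", frozenset(genes)),
        }
    )
    u = build_universe(g, m, db, min_genes=2)
    b = _trait_for(g, n_samples // 2)
    return g, u, b


class TestResampling:
    def test_exhaustive_enumeration_matches_monte_carlo(self, rng):
        """All C(6,3)=20 dummy triples vs the sampled null."""
        g, u, b = tiny_world(rng)
        engine = PodaEngine(g, u, b)
        ds_obs, _, n_genes, _ = engine.observed("target")
        exact_ds = []
        for combo in itertools.combinations(range(len(engine.genes)), n_genes):
            exact_ds.append(engine.ds_for_cols(engine.cols_for_genes(np.array(combo))))
        assert len(exact_ds) == 20
        p_exact = np.mean(np.array(exact_ds) >= ds_obs)
        B = 2000
        res = engine.resample("target", B=B, seed=11)
        se = np.sqrt(p_exact * (1 - p_exact) / B)
        assert abs(res.p_ds - p_exact) <= 3 * max(se, 1e-9)

    def test_degenerate_constant_genotypes_give_p_one(self):
        d = np.tile(np.array([0.0, 1, 2, 0, 1, 2])[:, None], (1, 8))
        d[0, :] = 0  # keep SNPs polymorphic but identical across columns
        g = poda.GenotypeMatrix.from_dosage([f"S{i}" for i in range(6)], [f"rs{j}" for j in range(8)], d)
        m = SnpGeneMap({f"rs{j}": {f"G{j % 4}"} for j in range(8)})
        db = PathwayDB({"pw": Pathway("pw", "s", frozenset({"G0", "G1"})),
                        "all": Pathway("all", "s", frozenset({f"G{i}" for i in range(4)}))})
        u = build_universe(g, m, db, min_genes=2)
        b = _trait_for(g, 3)
        res = resample_pds(g, u, b, "pw", B=50, seed=1)
        assert res.p_ds == 1.0  # every dummy DS ties the observed DS

    def test_reproducible_and_order_independent(self, rng):
        g, u, b = tiny_world(rng, n_samples=24)
        r1 = resample_pds(g, u, b, "target", B=100, seed=5)
        engine = PodaEngine(g, u, b)
        engine.resample("rest", B=100, seed=5)  # interleave another pathway
        r2 = engine.resample("target", B=100, seed=5)
        assert r1.p_ds == r2.p_ds and r1.ds == r2.ds

    def test_pathway_larger_than_universe_rejected(self, rng):
        g, u, b = tiny_world(rng, n_genes=6, pathway_genes=6)
        engine = PodaEngine(g, u, b)
        engine.genes = engine.genes[:4]  # sampling pool smaller than the pathway
        with pytest.raises(ValueError, match="smaller than pathway"):
            engine.resample("rest", B=10, seed=0)

    def test_unknown_pathway_rejected(self, rng):
        g, u, b = tiny_world(rng)
        with pytest.raises(ValueError, match="not retained"):
            resample_pds(g, u, b, "missing_pathway", B=10, seed=0)

    def test_keep_null_retains_dummy_draws(self, rng):
        g, u, b = tiny_world(rng)
        res = resample_pds(g, u, b, "target", B=25, seed=2, keep_null=True)
        assert res.dummy_ds is not None and len(res.dummy_ds) == 25
        assert res.p_ds == np.mean(res.dummy_ds >= res.ds)

    def test_add_one_correction(self, rng):
        g, u, b = tiny_world(rng)
        res = resample_pds(g, u, b, "target", B=40, seed=3)
        count = round(res.p_ds * 40)
        assert res.p_ds_corrected == pytest.approx((1 + count) / 41)


class TestEngineEquivalence:
    def test_fast_path_matches_public_distance_scores(self, rng):
        """Count-based distance sums equal the pairwise-matrix computation."""
        g, u, b = tiny_world(rng, n_samples=40, n_genes=8, pathway_genes=4)
        engine = PodaEngine(g, u, b)
        dsv = engine.distance_score_set("target")
        ref = distance_scores(g, dsv.snp_set, b)
        np.testing.assert_allclose(dsv.s, ref.s, atol=1e-12)

    def test_constant_snp_leaves_ds_sign_unchanged(self, rng):
        g = random_genotypes(rng, 20, 5)
        b = _trait_for(g, 8)
        res = distance_scores(g, g.snp_ids, b)
        d2 = np.hstack([g.dosage, np.ones((20, 1))])
        d2[0, -1] = 1.0
        g2 = poda.GenotypeMatrix.from_dosage(g.samples, g.snp_ids + ["const"], d2)
        res2 = distance_scores(g2, g2.snp_ids, b)
        assert np.sign(distinction_score(res)) == np.sign(distinction_score(res2))
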