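"""cis pairing, marginal association, permutations, FDR, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from apatwas.apaquant import UtrRegion
from apatwas.aqtlmap import (
    annotate_qq,
    cis_pairs,
    enrichment_or,
    gene_empirical_p,
    map_aqtl,
    marginal_assoc,
    qvalues,
)
from apatwas.simdata import GenotypeMatrix, Variant, sim_genotypes


def toy_genotypes(positions, chrom="1", n=4, seed=0):
    rng = np.random.default_rng(seed)
    variants = [Variant(chrom, p, f"v{i}", "A", "G", 0.3) for i, p in enumerate(positions)]
    d = rng.integers(0, 3, size=(n, len(positions))).astype(float)
    d[0] = 1.0  # guarantee polymorphism regardless of draw
    return GenotypeMatrix(d, variants, [f"s{i}" for i in range(n)])


class TestCisPairs:
    def test_boundary_inclusion_closed_interval(self):
        region = UtrRegion("1", 2_000_000, 2_000_400, "+", "G0", "T0")
        # 0-based coordinate of the variant = start - window -> included
        G = toy_genotypes([1_000_001])  # 1-based pos; 0-based 1_000_000 = start - 1e6
        pairs = cis_pairs([region], G, window=1_000_000)
        assert len(pairs) == 1

    def test_boundary_exclusion_one_past(self):
        region = UtrRegion("1", 2_000_000, 2_000_400, "+", "G0", "T0")
        G = toy_genotypes([1_000_000])  # 0-based 999_999: window+1 away
        assert cis_pairs([region], G, window=1_000_000).empty

    def test_counts_match_bruteforce_interval_oracle(self):
        rng = np.random.default_rng(1)
        regions = [
            UtrRegion("1", int(s), int(s) + 400, "+", f"G{i}", f"T{i}")
            for i, s in enumerate(rng.integers(0, 5_000_000, 3))
        ]
        positions = sorted(int(p) for p in rng.choice(6_000_000, 10, replace=False))
        G = toy_genotypes(positions)
        window = 1_000_000
        got = len(cis_pairs(regions, G, window=window))
        expected = sum(
            1
            for r in regions
            for p in positions
            if r.start - window <= p - 1 <= r.end + window - 1
        )
        assert got == expected

    def test_different_chromosome_excluded(self):
        region = UtrRegion("2", 100, 500, "+", "G0", "T0")
        G = toy_genotypes([200])
        assert cis_pairs([region], G).empty


class TestMarginalAssoc:
    def test_noiseless_fit(self):
        g = np.array([0, 1, 2, 0, 1, 2], dtype=float)
        rec = marginal_assoc(0.5 * g, g)
        assert rec.beta == pytest.approx(0.5)
        assert rec.p_nominal < 1e-200 or rec.se < 1e-12

    def test_matches_hand_computed_ols_on_six_points(self):
        g = np.array([0.0, 0.0, 1.0, 1.0, 2.0, 2.0])
        y = np.array([1.1, 0.9, 1.6, 1.4, 2.2, 1.8])
        rec = marginal_assoc(y, g)
        # independent closed-form oracle
        b = np.cov(g, y, ddof=1)[0, 1] / np.var(g, ddof=1)
        resid = (y - y.mean()) - b * (g - g.mean())
        s2 = resid @ resid / 4
        se = np.sqrt(s2 / ((g - g.mean()) @ (g - g.mean())))
        t = b / se
        p = 2 * stats.t.sf(abs(t), 4)
        assert rec.beta == pytest.approx(b, abs=1e-12)
        assert rec.se == pytest.approx(se, abs=1e-12)
        assert rec.p_nominal == pytest.approx(p, abs=1e-12)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(2)
        ps = []
        g = rng.integers(0, 3, 100).astype(float)
        for _ in range(1000):
            ps.append(marginal_assoc(rng.normal(size=100), g).p_nominal)
        frac = np.mean(np.array(ps) < 0.05)
        assert 0.03 <= frac <= 0.07

    def test_monomorphic_skipped(self):
        assert marginal_assoc(np.arange(5.0), np.ones(5)) is None

    def test_listwise_missing(self):
        y = np.array([1.0, np.nan, 2.0, 3.0, 4.0, 1.0])
        g = np.array([0.0, 1.0, np.nan, 2.0, 1.0, 0.0])
        rec = marginal_assoc(y, g)
        assert rec.n == 4


class TestGeneEmpiricalP:
    def test_floor_when_observed_beats_all_permutations(self):
        rng = np.random.default_rng(3)
        n = 200
        g = rng.integers(0, 3, n).astype(float)
        y = 0.8 * g + rng.normal(0, 0.1, n)
        res = gene_empirical_p(y, g[:, None], n_perm=1000, seed=0)
        assert res.empirical_p == pytest.approx(1 / 1001)

    def test_seed_determinism(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=80)
        X = rng.integers(0, 3, size=(80, 10)).astype(float)
        a = gene_empirical_p(y, X, n_perm=200, seed=5)
        b = gene_empirical_p(y, X, n_perm=200, seed=5)
        assert a.empirical_p == b.empirical_p and a.lead_variant == b.lead_variant

    def test_bounds_never_zero_never_above_one(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=50)
        X = rng.integers(0, 3, size=(50, 5)).astype(float)
        res = gene_empirical_p(y, X, n_perm=100, seed=1)
        assert 1 / 101 <= res.empirical_p <= 1.0


class TestQvalues:
    def test_all_ones(self):
        np.testing.assert_allclose(qvalues(np.ones(5)), np.ones(5))

    def test_bh_hand_computation(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        # step-up: q_i = min_{j>=i} p_j * m / j = 0.04 for all
        np.testing.assert_allclose(qvalues(p, method="bh"), [0.04, 0.04, 0.04, 0.04])

    def test_storey_with_pi0_one_equals_bh(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(0.6, 1.0, 50)  # all p > lambda forces pi0 -> 1 (capped)
        np.testing.assert_allclose(qvalues(p, method="storey"), qvalues(p, method="bh"))

    def test_order_invariance(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=30)
        perm = rng.permutation(30)
        np.testing.assert_allclose(qvalues(p)[perm], qvalues(p[perm]))

    def test_invalid_p_raises(self):
        with pytest.raises(ValueError):
            qvalues(np.array([0.0, 0.5]))


class TestAnnotateQq:
    def test_full_annotation_equals_control(self):
        rng = np.random.default_rng(8)
        p = pd.Series(rng.uniform(size=500), index=[f"rs{i}" for i in range(500)])
        table, lam = annotate_qq(p, {"all": set(p.index), "ctrl": set(p.index)})
        a = table[table["set"] == "all"].reset_index(drop=True)
        b = table[table["set"] == "ctrl"].reset_index(drop=True)
        np.testing.assert_allclose(a["observed_neglog10p"], b["observed_neglog10p"])

    def test_null_lambda_near_one(self):
        rng = np.random.default_rng(9)
        p = pd.Series(rng.uniform(size=10_000), index=[f"rs{i}" for i in range(10_000)])
        _, lam = annotate_qq(p, {"all": set(p.index)})
        assert abs(lam["all"] - 1.0) < 0.05

    def test_planted_enrichment_dominates_control(self):
        rng = np.random.default_rng(10)
        n = 4000
        ids = [f"rs{i}" for i in range(n)]
        z = rng.normal(size=n)
        ann = set(ids[: n // 4])
        z[: n // 4] = rng.normal(1.0, 1.0, n // 4)
        p = pd.Series(2 * stats.norm.sf(np.abs(z)), index=ids)
        table, _ = annotate_qq(p, {"annotated": ann, "control": set(ids)})
        a = table[table["set"] == "annotated"]
        b = table[table["set"] == "control"]
        qs = np.linspace(0.1, 0.9, 9)
        qa = np.quantile(a["observed_neglog10p"], qs)
        qb = np.quantile(b["observed_neglog10p"], qs)
        assert np.all(qa >= qb)

    def test_empty_intersection_warns(self):
        p = pd.Series([0.5], index=["rs0"])
        table, lam = annotate_qq(p, {"none": {"rsX"}})
        assert np.isnan(lam["none"]) and table.empty


class TestEnrichmentOr:
    def test_identical_sets_strong_enrichment(self):
        background = {f"rs{i}" for i in range(200)}
        sig = {f"rs{i}" for i in range(40)}
        res = enrichment_or(sig, sig, background, seed=0)
        assert res["odds_ratio"] > 1 and res["ci_low"] > 1

    def test_disjoint_sets_depleted(self):
        background = {f"rs{i}" for i in range(200)}
        sig = {f"rs{i}" for i in range(40)}
        ann = {f"rs{i}" for i in range(40, 80)}
        res = enrichment_or(sig, ann, background, seed=0)
        assert res["odds_ratio"] < 1

    def test_null_coverage(self):
        rng = np.random.default_rng(11)
        cover = 0
        reps = 60
        ids = [f"rs{i}" for i in range(300)]
        for rep in range(reps):
            sig = set(np.array(ids)[rng.random(300) < 0.2])
            ann = set(np.array(ids)[rng.random(300) < 0.3])
            res = enrichment_or(sig, ann, set(ids), n_boot=200, seed=rep)
            if res["ci_low"] <= 1.0 <= res["ci_high"]:
                cover += 1
        assert cover / reps >= 0.9

    def test_background_must_contain_sets(self):
        with pytest.raises(ValueError):
            enrichment_or({"a"}, {"b"}, {"b"})


class TestMapAqtl:
    def test_planted_signal_found_with_low_q(self):
        G = sim_genotypes(150, 10, ld_rho=0.3, seed=12, start_pos=400_000)
        rng = np.random.default_rng(13)
        regions = [UtrRegion("1", 500_000, 500_400, "+", "G0", "T0")]
        y = 0.5 * G.dosages[:, 4] + rng.normal(0, 0.5, 150)
        pheno = pd.DataFrame(
            [y - y.mean()],
            index=pd.MultiIndex.from_tuples([("G0", "T0")], names=["gene_id", "transcript_id"]),
            columns=G.sample_ids,
        )
        pairs, genes = map_aqtl(pheno, G, regions, n_perm=200, seed=1)
        assert len(pairs) == 10
        assert genes.iloc[0]["empirical_p"] <= 1 / 201 * 2
        assert genes.iloc[0]["lead_variant"] == G.variants[4].id
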