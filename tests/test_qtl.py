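"""Rank-normal transform, covariate-adjusted OLS, permutation FDR,
eQTL overlap, GWAS intersection and LD pruning."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from editome.qtl import (
    clinical_association_scan,
    edqtl_scan,
    encode_covariates,
    eqtl_overlap,
    gwas_intersect,
    ld_prune,
    ols_association,
    rank_normal,
    _batch_ols,
)
from editome.simulate import simulate_editing_matrix


class TestRankNormal:
    def test_three_distinct_values_normal_quantiles(self):
        out = rank_normal([10.0, 30.0, 20.0], seed=0)
        expected = stats.norm.ppf([1 / 6, 5 / 6, 3 / 6])
        assert np.allclose(out, expected, atol=1e-12)

    def test_matches_offset_rank_formula_exactly(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=101)  # distinct with probability 1
        out = rank_normal(x, seed=0)
        ranks = stats.rankdata(x)
        expected = stats.norm.ppf((ranks - 0.5) / x.size)
        assert np.allclose(out, expected, atol=1e-12)

    def test_median_of_odd_n_is_zero(self):
        out = rank_normal([5.0, 1.0, 9.0, 3.0, 7.0], seed=0)
        assert out[np.argsort([5.0, 1.0, 9.0, 3.0, 7.0])[2]] == 0.0

    def test_moments_at_n_1000(self):
        rng = np.random.default_rng(3)
        out = rank_normal(rng.exponential(size=1000), seed=1)
        assert abs(out.mean()) < 0.05
        assert abs(out.var() - 1) < 0.05

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=50)
        assert np.allclose(rank_normal(x, 7), rank_normal(np.exp(x), 7))

    def test_missing_values_stay_missing(self):
        out = rank_normal([1.0, np.nan, 2.0, 3.0], seed=0)
        assert np.isnan(out[1]) and np.isfinite(out[[0, 2, 3]]).all()

    def test_ties_broken_randomly_but_reproducibly(self):
        x = [1.0, 1.0, 1.0, 2.0]
        a = rank_normal(x, seed=5)
        b = rank_normal(x, seed=5)
        assert np.array_equal(a, b)
        assert len({round(v, 9) for v in a[:3]}) == 3  # distinct ranks

    def test_all_identical_warns(self):
        with pytest.warns(UserWarning):
            rank_normal([2.0, 2.0, 2.0], seed=0)


class TestOls:
    def test_exact_fit(self):
        r = ols_association([2.0, 4.0, 6.0, 9.0], [1.0, 2.0, 3.0, 4.5])
        assert r.beta == pytest.approx(2.0)
        assert r.r_squared == pytest.approx(1.0)

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(6)
        n = 80
        x = rng.normal(size=n)
        C = pd.DataFrame({"c1": rng.normal(size=n), "c2": rng.normal(size=n)})
        y = 0.5 * x + 0.3 * C["c1"] + rng.normal(size=n)
        ours = ols_association(y, x, C)
        D = sm.add_constant(np.column_stack([x, C]))
        ref = sm.OLS(y, D).fit()
        assert ours.beta == pytest.approx(ref.params.iloc[1], rel=1e-10)
        assert ours.t_statistic == pytest.approx(ref.tvalues.iloc[1], rel=1e-10)
        assert ours.p_value == pytest.approx(ref.pvalues.iloc[1], rel=1e-10)
        assert ours.r_squared == pytest.approx(ref.rsquared, rel=1e-10)

    def test_closed_form_two_variable_case(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=40)
        y = 1.5 * x + rng.normal(size=40)
        r = ols_association(y, x)
        beta_hat = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        assert r.beta == pytest.approx(beta_hat, rel=1e-10)
        assert r.r_squared == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2, rel=1e-10)

    def test_planted_beta_recovered_within_3se(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=200)
        y = 0.5 * x + rng.normal(size=200)
        r = ols_association(y, x)
        se = r.beta / r.t_statistic
        assert abs(r.beta - 0.5) < 3 * se

    def test_null_p_values_uniform(self):
        """KS check: two-sided p of an unrelated regressor is U(0,1)."""
        rng = np.random.default_rng(9)
        n, reps = 500, 1000
        x = rng.normal(size=n)
        Y = rng.normal(size=(n, reps))
        _, _, p, _ = _batch_ols(Y, x, None)
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_rank_deficient_names_columns(self):
        x = np.arange(10.0)
        C = pd.DataFrame({"dup": x})
        with pytest.raises(ValueError, match="collinear"):
            ols_association(np.ones(10), x, C)

    def test_categorical_covariates_one_hot(self):
        df = pd.DataFrame({"age": [50.0, 60.0], "batch": ["b1", "b2"]})
        enc = encode_covariates(df)
        assert list(enc.columns) == ["age", "batch_b2"]
        assert enc["batch_b2"].tolist() == [0.0, 1.0]


class TestPermutationCalibration:
    def test_null_adjusted_p_is_uniform_at_020(self):
        m, G, meta, cov, _ = simulate_editing_matrix(
            n_sites=500, n_samples=200, seed=21
        )
        res = edqtl_scan(m, G, meta, cov, n_perm=200, seed=22).results
        frac = (res["adjusted_p"] < 0.20).mean()
        se = np.sqrt(0.2 * 0.8 / len(res))
        assert abs(frac - 0.20) <= 3 * se

    def test_monomorphic_snp_excluded(self):
        m, G, meta, cov, _ = simulate_editing_matrix(n_sites=5, n_samples=60,
                                                     seed=23)
        G["mono"] = 0
        meta.loc["mono"] = {"chrom": "chr1", "pos": 999, "effect_allele": "G"}
        res = edqtl_scan(m, G, meta, cov, n_perm=20, seed=0).results
        assert "mono" not in set(res["snp"])

    def test_genotype_group_condition_recorded(self):
        m, G, meta, cov, _ = simulate_editing_matrix(n_sites=3, n_samples=60,
                                                     seed=24)
        # one carrier only: second-largest dosage group far below 20
        G["rare"] = 0
        G.iloc[0, G.columns.get_loc("rare")] = 1
        G["rare"] += np.where(np.arange(60) < 12, 1, 0)  # MAF ~0.1, group of 12
        meta.loc["rare"] = {"chrom": "chr2", "pos": 50, "effect_allele": "G"}
        res = edqtl_scan(m, G, meta, cov, n_perm=20, seed=0)
        assert any(snp == "rare" for _, snp, _ in res.skipped)

    def test_cis_trans_by_chromosome(self):
        m, G, meta, cov, _ = simulate_editing_matrix(n_sites=4, n_samples=60,
                                                     seed=25)
        meta.loc[:, "chrom"] = "chr2"
        res = edqtl_scan(m, G, meta, cov, n_perm=20, seed=0).results
        assert (res["cis_trans"] == "trans").all()  # sites live on chr1

    def test_index_edqtl_is_min_p_per_site(self):
        m, G, meta, cov, _ = simulate_editing_matrix(
            n_sites=10, n_samples=80, beta=0.2, n_effect_sites=10, seed=26
        )
        G["extra"] = np.random.default_rng(0).binomial(2, 0.4, 80)
        meta.loc["extra"] = {"chrom": "chr1", "pos": 77, "effect_allele": "G"}
        res = edqtl_scan(m, G, meta, cov, n_perm=50, seed=1).results
        for site, grp in res.groupby("site"):
            assert grp.loc[grp["index_edqtl"], "p_value"].iloc[0] == grp["p_value"].min()


class TestClinicalScan:
    def build(self, r2_strength, seed=30):
        rng = np.random.default_rng(seed)
        m, G, meta, cov, _ = simulate_editing_matrix(
            n_sites=10, n_samples=100, ratio_sd=0.15, seed=seed
        )
        site0 = m.ratios.index[0]
        signal = m.ratios.loc[site0].fillna(m.ratios.loc[site0].mean())
        noise = rng.normal(0, 1, 100)
        traits = pd.DataFrame(
            {"t": r2_strength * (signal - signal.mean()) / signal.std() + noise},
            index=m.ratios.columns,
        )
        return m, traits, cov, site0

    def test_strong_planted_effect_flagged(self):
        m, traits, cov, site0 = self.build(r2_strength=3.0)
        res = clinical_association_scan(
            m, traits, cov, n_perm=1000, seed=31, min_samples=50
        ).results
        row = res[(res.site == site0) & (res.trait == "t")].iloc[0]
        assert row.r_squared > 0.4 and row.adjusted_p < 0.05 and row.significant

    def test_weak_effect_fails_r2_criterion(self):
        m, traits, cov, site0 = self.build(r2_strength=0.5)
        res = clinical_association_scan(
            m, traits, cov, n_perm=200, seed=32, min_samples=50
        ).results
        row = res[(res.site == site0) & (res.trait == "t")].iloc[0]
        assert row.r_squared < 0.4 and not row.significant

    def test_expression_gate_blocks_confounded_site(self):
        m, traits, cov, site0 = self.build(r2_strength=3.0)
        # host-gene expression built to track the trait
        expression = pd.DataFrame(
            {"g1": traits["t"] * 2.0 + 0.01}, index=traits.index
        )
        res = clinical_association_scan(
            m, traits, cov, expression=expression, site_genes={site0: ["g1"]},
            n_perm=200, seed=33, min_samples=50,
        ).results
        row = res[(res.site == site0) & (res.trait == "t")].iloc[0]
        assert not row.expression_gate_ok and not row.significant


class TestEqtlOverlap:
    def test_planted_expression_effect_flagged(self):
        rng = np.random.default_rng(40)
        n = 120
        samples = [f"S{i:03d}" for i in range(n)]
        G = pd.DataFrame({"rs1": rng.binomial(2, 0.4, n)}, index=samples)
        cov = pd.DataFrame({"age": rng.normal(60, 8, n)}, index=samples)
        expr = pd.DataFrame(
            {"gA": 10 + 3.0 * G["rs1"] + rng.normal(0, 1, n),
             "gB": 10 + rng.normal(0, 1, n)},
            index=samples,
        )
        edqtl = pd.DataFrame(
            [{"site": "s1", "snp": "rs1"}, {"site": "s2", "snp": "rs1"}]
        )
        out = eqtl_overlap(edqtl, expr, G, cov,
                           site_genes={"s1": ["gA"], "s2": ["gB"]})
        assert out.loc[0, "eqtl"] == True  # noqa: E712
        assert out.loc[1, "eqtl"] == False  # noqa: E712

    def test_site_without_gene_has_missing_flag(self):
        rng = np.random.default_rng(41)
        samples = ["a", "b", "c", "d", "e", "f", "g", "h"]
        G = pd.DataFrame({"rs1": rng.binomial(2, 0.5, 8)}, index=samples)
        cov = pd.DataFrame({"age": rng.normal(size=8)}, index=samples)
        expr = pd.DataFrame({"gA": rng.normal(size=8)}, index=samples)
        edqtl = pd.DataFrame([{"site": "s1", "snp": "rs1"}])
        out = eqtl_overlap(edqtl, expr, G, cov, site_genes={})
        assert out["eqtl"].isna().all()

    def test_bh_adjustment_by_hand(self):
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.01, 0.02, 0.04], method="fdr_bh")[1]
        assert np.allclose(adj, [0.03, 0.03, 0.04])


class TestGwasIntersect:
    def catalog(self):
        return pd.DataFrame(
            {
                "snp": ["rs1", "rs1", "rs2", "rs3"],
                "trait": ["LDL", "LDL", "HDL", "T2D"],
                "p_value": [1e-9, 5e-10, 1e-7, 2e-12],
            }
        )

    def test_threshold_strict(self):
        out = gwas_intersect(["rs1", "rs2"], self.catalog())
        assert set(out["snp"]) == {"rs1"}  # rs2 at 1e-7 fails P < 1e-8

    def test_duplicates_collapsed_to_min_p(self):
        out = gwas_intersect(["rs1"], self.catalog())
        assert len(out) == 1 and out.loc[0, "p_value"] == 5e-10

    def test_empty_intersection(self):
        assert gwas_intersect(["rs99"], self.catalog()).empty


def brute_force_greedy(snps, genotypes, positions, window_bp, r2):
    """Independent oracle: explicit pairwise scan in position order."""
    order = sorted(snps, key=lambda s: (positions.loc[s, "chrom"],
                                        positions.loc[s, "pos"]))
    kept = []
    for s in order:
        drop = False
        for k in kept:
            same = positions.loc[k, "chrom"] == positions.loc[s, "chrom"]
            close = positions.loc[s, "pos"] - positions.loc[k, "pos"] <= window_bp
            if same and close:
                r = np.corrcoef(genotypes[k], genotypes[s])[0, 1]
                if r * r > r2:
                    drop = True
        if not drop:
            kept.append(s)
    return kept


class TestLdPrune:
    def geno(self, vectors):
        return pd.DataFrame({f"s{i}": v for i, v in enumerate(vectors)})

    def pos(self, n, spacing=100):
        return pd.DataFrame(
            {"chrom": "chr1", "pos": [spacing * i for i in range(n)]},
            index=[f"s{i}" for i in range(n)],
        )

    def test_identical_dosages_later_removed(self):
        v = [0, 1, 2, 1, 0, 2, 1, 1]
        G = self.geno([v, v])
        assert ld_prune(["s0", "s1"], G, self.pos(2)) == ["s0"]

    def test_independent_snps_all_retained(self):
        rng = np.random.default_rng(50)
        G = self.geno([rng.binomial(2, 0.5, 100) for _ in range(4)])
        assert ld_prune(list(G.columns), G, self.pos(4)) == list(G.columns)

    def test_chain_keeps_first_and_third(self):
        rng = np.random.default_rng(51)
        a = rng.binomial(1, 0.5, 200).astype(float)
        b = a.copy()
        flip = rng.random(200) < 0.05
        b[flip] = 1 - b[flip]  # r2(a,b) ~ 0.8
        c = rng.binomial(1, 0.5, 200).astype(float)
        G = self.geno([a, b, c])
        r2ab = np.corrcoef(a, b)[0, 1] ** 2
        assert r2ab > 0.6
        assert ld_prune(["s0", "s1", "s2"], G, self.pos(3)) == ["s0", "s2"]

    def test_window_limits_comparisons(self):
        v = [0, 1, 2, 1, 0, 2]
        G = self.geno([v, v])
        pos = self.pos(2, spacing=500_000)  # beyond the 400 kb window
        assert ld_prune(["s0", "s1"], G, pos) == ["s0", "s1"]

    def test_matches_brute_force_oracle_on_all_triples(self):
        """Every 3-SNP configuration drawn from a dosage-vector grid must
        reproduce the explicit greedy oracle."""
        rng = np.random.default_rng(52)
        base = rng.binomial(2, 0.5, 30).astype(float)
        pool = [base]
        for flips in (1, 3, 8, 15):
            v = base.copy()
            idx = rng.choice(30, flips, replace=False)
            v[idx] = rng.integers(0, 3, flips)
            pool.append(v)
        pool.append(rng.binomial(2, 0.3, 30).astype(float))
        names = [f"s{i}" for i in range(3)]
        pos = self.pos(3)
        for i in range(len(pool)):
            for j in range(len(pool)):
                for k in range(len(pool)):
                    G = self.geno([pool[i], pool[j], pool[k]])
                    got = ld_prune(names, G, pos)
                    want = brute_force_greedy(names, G, pos, 400_000, 0.6)
                    assert got == want, (i, j, k)

    def test_idempotent(self):
        rng = np.random.default_rng(53)
        G = self.geno([rng.binomial(2, 0.5, 50) for _ in range(6)])
        pos = self.pos(6)
        kept = ld_prune(list(G.columns), G, pos)
        assert ld_prune(kept, G, pos) == kept

    def test_missing_snp_raises(self):
        G = self.geno([[0, 1, 2]])
        with pytest.raises(KeyError):
            ld_prune(["s0", "sX"], G, self.pos(2))
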