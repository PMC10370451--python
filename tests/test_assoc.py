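"""Score test, association filters, BH correction and linkage pruning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lceqtl.assoc import (
    STATUS_MINCOUNT,
    STATUS_MINHIGH,
    STATUS_SMALL_N,
    STATUS_TESTED,
    STATUS_UNTESTABLE,
    apply_site_filters,
    bh_adjust,
    prune_hits,
    run_association_suite,
    score_test,
)
from lceqtl.io import PipelineConfig
from lceqtl.simulate import SimConfig, simulate_dataset


def ols_score_oracle(d, y, X):
    """Independent least-squares score statistic via statsmodels fits."""
    import statsmodels.api as sm

    null = sm.OLS(y, X).fit()
    r = null.resid
    d_resid = sm.OLS(d, X).fit().resid
    sigma2 = (r @ r) / len(y)
    return float((d_resid @ r) ** 2 / (sigma2 * (d_resid @ d_resid)))


class TestScoreTest:
    def test_perfect_association_certain_genotypes(self):
        rng = np.random.default_rng(0)
        d = rng.binomial(2, 0.4, size=50).astype(float)
        res = score_test(d, y=d)
        assert res.status == STATUS_TESTED
        assert res.p < 1e-10

    def test_agrees_with_least_squares_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            n = 40
            d = rng.binomial(2, 0.3, size=n).astype(float)
            C = rng.normal(size=(n, 2))
            y = 0.5 * d + C @ [1.0, -0.5] + rng.normal(size=n)
            res = score_test(d, y, covariates=C)
            X = np.column_stack([np.ones(n), C])
            assert res.T == pytest.approx(ols_score_oracle(d, y, X), rel=1e-8)

    def test_constant_dosage_untestable(self):
        rng = np.random.default_rng(2)
        res = score_test(np.ones(30), rng.normal(size=30))
        assert res.status == STATUS_UNTESTABLE
        assert np.isnan(res.p)

    def test_dosage_collinear_with_covariate_untestable(self):
        rng = np.random.default_rng(3)
        d = rng.binomial(2, 0.5, size=40).astype(float)
        res = score_test(d, rng.normal(size=40), covariates=d)
        assert res.status == STATUS_UNTESTABLE

    def test_too_few_complete_cases(self):
        y = np.array([1.0, np.nan, np.nan, 2.0])
        res = score_test(np.array([0.0, 1, 2, 1]), y)
        assert res.status == STATUS_SMALL_N

    def test_missing_cases_dropped(self):
        rng = np.random.default_rng(4)
        d = rng.binomial(2, 0.4, size=30).astype(float)
        y = rng.normal(size=30)
        y[:5] = np.nan
        res = score_test(d, y)
        assert res.n == 25

    def test_temperature_confounding_needs_covariate(self):
        # phenotype driven only by temperature; genotype weakly linked to
        # temperature by chance imbalance -> omitting the covariate inflates
        rng = np.random.default_rng(5)
        n, S = 60, 400
        temp = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        # make dosages temperature-structured (allele-frequency shift)
        p = np.where(temp == 0, 0.25, 0.55)
        y = 2.0 * temp + rng.normal(0, 0.5, size=n)
        p_with, p_without = [], []
        for _ in range(S):
            d = rng.binomial(2, p).astype(float)
            if d.std() == 0:
                continue
            p_with.append(score_test(d, y, covariates=temp).p)
            p_without.append(score_test(d, y).p)
        assert np.mean(np.array(p_with) < 0.05) < 0.10
        assert np.mean(np.array(p_without) < 0.05) > 0.5


class TestSiteFilters:
    def _certain_post(self, genotypes):
        g = np.asarray(genotypes)
        post = np.zeros((len(g), 3))
        post[np.arange(len(g)), g] = 1.0
        return post, g.astype(float)

    def test_all_hom_ref_fails_mincount(self):
        post, dos = self._certain_post([0] * 25)
        st_ = apply_site_filters(post, dos)
        assert not st_.min_count_ok
        assert st_.status == STATUS_MINCOUNT

    def test_two_strong_classes_pass(self):
        post, dos = self._certain_post([0] * 12 + [1] * 12)
        post = np.vstack([post, [[1 / 3, 1 / 3, 1 / 3]]])
        dos = np.append(dos, 1.0)  # flat individual at HWE-ish dosage
        st_ = apply_site_filters(post, dos)
        assert st_.status == STATUS_TESTED

    def test_nine_high_credible_hets_fail_minhigh(self):
        post, dos = self._certain_post([1] * 9 + [0] * 30)
        st_ = apply_site_filters(post, dos)
        assert not st_.min_high_ok

    def test_threshold_is_inclusive(self):
        post, dos = self._certain_post([1] * 10 + [0] * 30)
        st_ = apply_site_filters(post, dos)
        assert st_.min_high_ok and st_.min_count_ok


class TestBHAdjust:
    def test_closed_form_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_identity(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_adjusted_never_below_raw_and_capped(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=200)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-12) and np.all(q <= 1.0)

    def test_ties_keep_order(self):
        q = bh_adjust([0.5, 0.01, 0.5, 0.01])
        assert q[1] == q[3] and q[0] == q[2] and q[1] <= q[0]

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 0.0])
        with pytest.raises(ValueError):
            bh_adjust([1.5])


def _hits(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "p_raw"])


class TestPruneHits:
    def test_closer_weaker_hit_pruned(self):
        out = prune_hits(_hits([("chr1", 100, 1e-8), ("chr1", 400, 1e-5)]))
        assert list(out["pos"]) == [100]
        assert list(out["pruned_neighbors"]) == [1]

    def test_distant_hits_both_kept(self):
        out = prune_hits(_hits([("chr1", 100, 1e-8), ("chr1", 701, 1e-5)]))
        assert list(out["pos"]) == [100, 701]

    def test_window_boundary_inclusive(self):
        out = prune_hits(_hits([("chr1", 100, 1e-8), ("chr1", 600, 1e-5)]))
        assert list(out["pos"]) == [100]  # exactly 500 bp apart -> pruned

    def test_greedy_chain(self):
        out = prune_hits(
            _hits([("chr1", 0, 1e-3), ("chr1", 400, 1e-6), ("chr1", 800, 1e-2)])
        )
        assert list(out["pos"]) == [400]
        assert out.loc[0, "pruned_neighbors"] == 2

    def test_different_chromosomes_independent(self):
        out = prune_hits(_hits([("chr1", 100, 1e-8), ("chr2", 150, 1e-5)]))
        assert len(out) == 2

    @settings(max_examples=30, deadline=None)
    @given(st.randoms(use_true_random=False))
    def test_invariant_to_input_order(self, rnd):
        rng = np.random.default_rng(rnd.randrange(2**31))
        k = rng.integers(1, 9)
        rows = [
            ("chr1", int(rng.integers(0, 3000)), float(rng.uniform(1e-10, 0.05)))
            for _ in range(k)
        ]
        rows = list({(c, p): (c, p, v) for c, p, v in rows}.values())
        base = prune_hits(_hits(rows))
        perm = prune_hits(_hits(list(reversed(rows))))
        pd.testing.assert_frame_equal(base, perm)


class TestSuite:
    def test_planted_trait_snp_in_trait_hits(self):
        # a trait loaded on one module whose factor carries a planted SNP:
        # the SNP is directly associated with the trait
        cfg = SimConfig(
            n_individuals=250, n_pheno=250, n_expr=30, n_sites=400,
            n_modules=1, genes_per_module=8, n_trans_eqtl=1, n_cis_eqtl=0,
            maf_range=(0.2, 0.5), expr_temp_effect=0.0,
            trait_module_weight=1.0, trait_noise_sd=0.3, n_traits=1,
            mean_depth=30, seed=9,
        )
        data = simulate_dataset(cfg)
        res = run_association_suite(
            data.site_gls, phenotypes=data.phenotypes, individuals=data.individuals
        )
        planted_site = data.truth.planted.loc[0, "site_id"]
        trait_hits = res.hits[res.hits["phen_class"] == "trait"]
        assert planted_site in set(trait_hits["site_id"])

    def test_null_suite_has_few_hits(self):
        cfg = SimConfig(
            n_individuals=80, n_pheno=80, n_expr=40, n_sites=250,
            n_modules=2, genes_per_module=8, n_trans_eqtl=0, n_cis_eqtl=0,
            trait_module_weight=0.0, n_traits=4, mean_depth=10, seed=10,
        )
        data = simulate_dataset(cfg)
        res = run_association_suite(
            data.site_gls, phenotypes=data.phenotypes,
            expression_sets=[data.expression], individuals=data.individuals,
        )
        # with no planted effects the FDR-controlled hit count stays near zero
        assert len(res.hits) <= 3

    def test_adjustment_within_phenotype_and_invariants(self, small_dataset):
        res = run_association_suite(
            small_dataset.site_gls, phenotypes=small_dataset.phenotypes,
            expression_sets=[small_dataset.expression],
            individuals=small_dataset.individuals,
        )
        tested = res.tests[res.tests["status"] == STATUS_TESTED]
        assert (tested["p_adj"] >= tested["p_raw"] - 1e-12).all()
        assert (tested["T"] >= 0).all()
        for _, grp in res.hits.groupby("phenotype"):
            for chrom, sub in grp.groupby("chrom"):
                pos = np.sort(sub["pos"].to_numpy())
                assert (np.diff(pos) > 500).all()

    def test_small_phenotype_skipped(self, small_dataset):
        pheno = small_dataset.phenotypes
        data = pheno.data.copy()
        data["tiny"] = np.nan
        data.loc[data.index[:3], "tiny"] = [1.0, 2.0, 3.0]
        from lceqtl.io import PhenotypeTable

        table = PhenotypeTable(data=data, traits=pheno.traits + ["tiny"])
        res = run_association_suite(
            small_dataset.site_gls[:20], phenotypes=table,
            individuals=small_dataset.individuals,
        )
        assert "tiny" not in set(res.tests["phenotype"])
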