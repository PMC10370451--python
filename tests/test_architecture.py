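"""Cis/trans classification, hotspots, trans null, proximity, sharing, He."""

import numpy as np
import pandas as pd
import pytest

from lceqtl.architecture import (
    annotate_proximity,
    architecture_summary,
    classify_cis_trans,
    eqtl_me_consistency,
    expected_trans_test,
    find_hotspots,
    he_comparison,
    me_overlap_check,
    overlap_sets,
    sharing_test,
)


@pytest.fixture()
def genes():
    return pd.DataFrame(
        {
            "gene_id": ["gA", "gB", "tf1", "gC"],
            "chrom": ["chr1", "chr2", "chr1", "chr1"],
            "start": [90, 1, 10_000, 50_000],
            "end": [200, 500, 12_000, 51_000],
            "strand": ["+", "+", "-", "+"],
            "is_tf": [False, False, True, False],
        }
    )


def eqtl_frame(rows):
    return pd.DataFrame(rows, columns=["site_id", "chrom", "pos", "target"])


class TestClassifyCisTrans:
    def test_different_sequence_is_trans(self, genes):
        out = classify_cis_trans(
            eqtl_frame([("chr1_100", "chr1", 100, "gB")]), genes
        )
        assert out.loc[0, "classification"] == "trans"
        assert np.isnan(out.loc[0, "distance_bp"])

    def test_inside_gene_is_cis_distance_zero(self, genes):
        out = classify_cis_trans(
            eqtl_frame([("chr1_100", "chr1", 100, "gA")]), genes
        )
        assert out.loc[0, "classification"] == "cis"
        assert out.loc[0, "distance_bp"] == 0

    def test_distal_same_sequence_still_cis(self, genes):
        # the rule is sequence-level, not distance-level
        out = classify_cis_trans(
            eqtl_frame([("chr1_10000", "chr1", 10_000, "gA")]), genes
        )
        assert out.loc[0, "classification"] == "cis"
        assert out.loc[0, "distance_bp"] == 9_800  # to gA's end at 200

    def test_unknown_target_unclassified(self, genes):
        out = classify_cis_trans(
            eqtl_frame([("chr1_5", "chr1", 5, "nope")]), genes
        )
        assert out.loc[0, "classification"] == "unclassified"

    def test_trans_fraction_complements_cis(self, genes):
        rng = np.random.default_rng(0)
        rows = []
        for k in range(50):
            target = rng.choice(["gA", "gB", "gC"])
            chrom = rng.choice(["chr1", "chr2", "chr3"])
            rows.append((f"{chrom}_{k}", chrom, k + 1, target))
        out = classify_cis_trans(eqtl_frame(rows), genes)
        sub = out[out["classification"] != "unclassified"]
        n_cis = (sub["classification"] == "cis").sum()
        n_trans = (sub["classification"] == "trans").sum()
        assert n_cis + n_trans == len(sub)


class TestHotspots:
    def test_multi_target_snp_is_hotspot(self):
        eqtl = pd.DataFrame(
            {"site_id": ["s1", "s1", "s2"], "target": ["mA", "mB", "mA"]}
        )
        hs = find_hotspots(eqtl)
        assert hs.hotspots == ["s1"]
        assert hs.per_snp["s1"] == 2 and hs.per_snp["s2"] == 1
        assert hs.snp_max == 2
        assert hs.per_mrna["mA"] == 2

    def test_single_target_not_hotspot(self):
        hs = find_hotspots(pd.DataFrame({"site_id": ["s1"], "target": ["mA"]}))
        assert hs.hotspots == []

    def test_empty_catalog(self):
        hs = find_hotspots(pd.DataFrame(columns=["site_id", "target"]))
        assert hs.hotspots == [] and len(hs.per_snp) == 0


class TestExpectedTransTest:
    def test_all_cis_on_many_sequences_rejected(self):
        # 24 equal sequences, sites uniform: expected trans = 23/24 of total
        site_counts = pd.Series(100, index=[f"chr{k}" for k in range(1, 25)])
        df = pd.DataFrame(
            {
                "classification": ["cis"] * 48,
                "target_chrom": [f"chr{k % 24 + 1}" for k in range(48)],
            }
        )
        res = expected_trans_test(df, site_counts)
        assert res.exp_trans == pytest.approx(48 * 23 / 24)
        assert res.p < 0.01
        assert not res.undefined

    def test_single_eqtl_low_count_flagged(self):
        site_counts = pd.Series([50, 50], index=["chr1", "chr2"])
        df = pd.DataFrame({"classification": ["trans"], "target_chrom": ["chr1"]})
        res = expected_trans_test(df, site_counts)
        assert res.low_count
        assert np.isfinite(res.chi2)

    def test_undefined_when_no_cis_expected(self):
        site_counts = pd.Series([50], index=["chr1"])
        df = pd.DataFrame({"classification": ["trans"], "target_chrom": ["chrX"]})
        res = expected_trans_test(df, site_counts)
        assert res.undefined

    def test_null_placement_near_nominal_rejection(self):
        # targets and sites placed independently: the test should reject
        # at about the nominal 5% rate (slightly conservative)
        rng = np.random.default_rng(1)
        seqs = [f"chr{k}" for k in range(1, 11)]
        site_counts = pd.Series(rng.multinomial(2000, np.ones(10) / 10), index=seqs)
        frac = site_counts / site_counts.sum()
        rejections = 0
        reps = 200
        for _ in range(reps):
            tchrom = rng.choice(seqs, size=300)
            p_cis = frac[tchrom].to_numpy()
            is_cis = rng.random(300) < p_cis
            df = pd.DataFrame(
                {
                    "classification": np.where(is_cis, "cis", "trans"),
                    "target_chrom": tchrom,
                }
            )
            rejections += expected_trans_test(df, site_counts).p < 0.05
        assert 0.01 <= rejections / reps <= 0.10


class TestProximity:
    def test_boundary_4999_inside_window(self, genes):
        snps = pd.DataFrame({"chrom": ["chr1"], "pos": [10_000 - 4_999]})
        out = annotate_proximity(snps, genes, window=5000)
        assert out.loc[0, "near_tf"]

    def test_boundary_5001_outside_window(self, genes):
        snps = pd.DataFrame({"chrom": ["chr1"], "pos": [10_000 - 5_001]})
        out = annotate_proximity(snps, genes, window=5000)
        assert not out.loc[0, "near_tf"]

    def test_inside_non_tf_gene(self, genes):
        snps = pd.DataFrame({"chrom": ["chr1"], "pos": [150]})
        out = annotate_proximity(snps, genes, window=5000)
        assert out.loc[0, "annotation"] == "genic"
        assert out.loc[0, "gene_ids"] == "gA"
        assert not out.loc[0, "near_tf"]

    def test_unannotated_sequence_intergenic(self, genes):
        snps = pd.DataFrame({"chrom": ["chr9"], "pos": [5]})
        out = annotate_proximity(snps, genes, window=5000)
        assert out.loc[0, "annotation"] == "intergenic"

    def test_overlapping_genes_all_reported(self, genes):
        extra = pd.concat(
            [genes, pd.DataFrame([{"gene_id": "gD", "chrom": "chr1", "start": 80,
                                   "end": 300, "strand": "+", "is_tf": False}])],
            ignore_index=True,
        )
        out = annotate_proximity(pd.DataFrame({"chrom": ["chr1"], "pos": [150]}), extra)
        assert set(out.loc[0, "gene_ids"].split(",")) == {"gA", "gD"}


class TestMeOverlap:
    def test_inside_member_gene_flagged(self, genes):
        modules = pd.Series({"gA": "M0", "gB": "M0", "gC": "M1"})
        hits = pd.DataFrame({"chrom": ["chr1"], "pos": [100], "target": ["M0"]})
        assert me_overlap_check(hits, modules, genes).iloc[0]

    def test_no_member_on_sequence_unflagged(self, genes):
        modules = pd.Series({"gB": "M0"})
        hits = pd.DataFrame({"chrom": ["chr1"], "pos": [100], "target": ["M0"]})
        assert not me_overlap_check(hits, modules, genes).iloc[0]

    def test_member_beyond_window_unflagged(self, genes):
        modules = pd.Series({"gC": "M0"})  # gC at chr1:50000-51000
        hits = pd.DataFrame({"chrom": ["chr1"], "pos": [40_000], "target": ["M0"]})
        assert not me_overlap_check(hits, modules, genes, window=5000).iloc[0]


class TestSharingTest:
    def _modules(self):
        return pd.Series(
            {"m1": "A", "m2": "A", "m3": "B", "m4": "B", "m5": "C", "m6": "C"}
        )

    def test_sharing_only_across_modules(self):
        # planted sharing across modules: among-mean exceeds within-mean
        rows = []
        mods = self._modules()
        tested = list(mods.index)
        pairs = [("m1", "m3"), ("m2", "m4"), ("m1", "m5"), ("m3", "m5"), ("m2", "m6")]
        for k, (a, b) in enumerate(pairs):
            rows += [{"site_id": f"s{k}", "target": a}, {"site_id": f"s{k}", "target": b}]
        res = sharing_test(pd.DataFrame(rows), mods, tested)
        assert res.among_mean > res.within_mean
        assert res.status == "ok"
        assert res.p < 0.1

    def test_universal_sharing_degenerate(self):
        mods = self._modules()
        rows = [{"site_id": "s0", "target": m} for m in mods.index]
        res = sharing_test(pd.DataFrame(rows), mods, list(mods.index))
        assert res.status == "degenerate"
        assert res.within_mean == 1.0 and res.among_mean == 1.0

    def test_no_sharing_degenerate_zero_means(self):
        mods = self._modules()
        rows = [{"site_id": f"s{k}", "target": m} for k, m in enumerate(mods.index)]
        res = sharing_test(pd.DataFrame(rows), mods, list(mods.index))
        assert res.status == "degenerate"
        assert res.within_mean == 0.0 and res.among_mean == 0.0

    def test_requires_two_modules(self):
        mods = pd.Series({"m1": "A", "m2": "A"})
        with pytest.raises(ValueError):
            sharing_test(pd.DataFrame(columns=["site_id", "target"]), mods, ["m1", "m2"])


class TestHeComparison:
    def test_identical_sets_no_difference(self):
        rng = np.random.default_rng(0)
        he = rng.uniform(0.1, 0.5, size=200)
        res = he_comparison(he, he, n_perm=2000, rng=rng)
        assert res.p_perm > 0.5
        assert res.focal_mean == pytest.approx(res.background_mean)

    def test_high_maf_focal_detected(self):
        rng = np.random.default_rng(1)
        background = 2 * rng.uniform(0.05, 0.5, 500) * (1 - rng.uniform(0.05, 0.5, 500))
        focal = 2 * rng.uniform(0.4, 0.5, 40) * (1 - rng.uniform(0.4, 0.5, 40))
        res = he_comparison(focal, background, n_perm=2000, rng=rng)
        assert res.focal_mean > res.background_mean
        assert res.p_t < 0.01
        assert res.p_perm < 0.01

    def test_tiny_focal_set_flags_t_but_permutes(self):
        rng = np.random.default_rng(2)
        res = he_comparison([0.49], rng.uniform(0.1, 0.5, 100), n_perm=500, rng=rng)
        assert not res.t_defined
        assert res.p_perm is not None

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            he_comparison([], [0.1, 0.2])


class TestOverlaps:
    def test_disjoint_catalogs_empty(self):
        out = overlap_sets({"trait": {"s1"}, "eqtl": {"s2"}, "me": {"s3"}})
        assert (out["n_overlap"] == 0).all()

    def test_shared_snp_reported(self):
        out = overlap_sets({"trait": {"s1", "s2"}, "eqtl": {"s2", "s3"}})
        assert out.loc[0, "n_overlap"] == 1 and out.loc[0, "members"] == "s2"

    def test_gene_level_overlap_without_snp_overlap(self, genes):
        # two different SNPs inside the same gene: gene-level hit, SNP-level miss
        cat_a = pd.DataFrame({"chrom": ["chr1"], "pos": [100], "site_id": ["sA"]})
        cat_b = pd.DataFrame({"chrom": ["chr1"], "pos": [150], "site_id": ["sB"]})
        ann_a = annotate_proximity(cat_a, genes)
        ann_b = annotate_proximity(cat_b, genes)
        snp_overlap = overlap_sets(
            {"a": set(cat_a["site_id"]), "b": set(cat_b["site_id"])}
        )
        gene_overlap = overlap_sets(
            {"a": set(ann_a["gene_ids"]), "b": set(ann_b["gene_ids"])}
        )
        assert snp_overlap.loc[0, "n_overlap"] == 0
        assert gene_overlap.loc[0, "n_overlap"] == 1

    def test_eqtl_me_consistency_flags_same_module(self):
        modules = pd.Series({"mA": "M0", "mB": "M1"})
        eqtl = pd.DataFrame({"site_id": ["s1", "s2"], "target": ["mA", "mB"]})
        me_hits = pd.DataFrame({"site_id": ["s1"], "target": ["M0"]})
        out = eqtl_me_consistency(eqtl, me_hits, modules)
        assert len(out) == 1 and out.loc[0, "mrna"] == "mA"
        none = eqtl_me_consistency(eqtl, pd.DataFrame({"site_id": ["s9"], "target": ["M0"]}), modules)
        assert none.empty


class TestSummary:
    def test_counts_recomputable_from_catalog(self, genes):
        rows = [
            ("chr1_100", "chr1", 100, "gA"),   # cis
            ("chr2_5", "chr2", 5, "gA"),       # trans
            ("chr2_9", "chr2", 9, "gB"),       # cis
            ("chr3_7", "chr3", 7, "gB"),       # trans
        ]
        classified = classify_cis_trans(eqtl_frame(rows), genes)
        hs = find_hotspots(classified)
        summary = architecture_summary(classified, hs)
        assert summary["n_cis"] == 2 and summary["n_trans"] == 2
        assert summary["trans_fraction"] == pytest.approx(0.5)
        assert summary["n_hotspots"] == len(hs.hotspots)
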