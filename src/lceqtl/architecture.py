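"""Regulatory-architecture analyses on the pruned eQTL catalog.

Everything here consumes the significant, pruned association catalogs and
the gene annotation:

* cis/trans classification at the sequence level — an eQTL is *trans*
  when its SNP sits on a different chromosome or scaffold than the target
  gene, *cis* otherwise (no distance cutoff by default; module-eigengene
  eQTL are never classified, since a module has no single location);
* hotspot detection — a SNP associated with more than one mRNA within a
  tissue;
* a chromosome-aware null for the trans fraction: under random site-
  target placement the probability an eQTL is trans given its target's
  sequence s is 1 - (tested sites on s) / (total tested sites); observed
  vs expected cis/trans counts are compared by a 1-df goodness-of-fit
  chi-square;
* genic/intergenic annotation and transcription-factor proximity
  (within or <= 5 kb of a TF gene, inclusive);
* module-overlap checks for eigengene eQTL, the within- vs among-module
  eQTL-sharing t-test, heterozygosity comparisons between SNP sets, and
  catalog overlap (intersection) reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "classify_cis_trans",
    "HotspotSummary",
    "find_hotspots",
    "TransTestResult",
    "expected_trans_test",
    "annotate_proximity",
    "me_overlap_check",
    "SharingTestResult",
    "sharing_test",
    "HeComparisonResult",
    "he_comparison",
    "overlap_sets",
    "architecture_summary",
]


# ---------------------------------------------------------------------------
# cis / trans

def classify_cis_trans(eqtl: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Label each single-mRNA eQTL cis or trans and measure distance.

    ``eqtl`` needs ``chrom, pos, target`` (target = gene id); ``genes``
    is an annotation table as from :func:`lceqtl.io.read_gff_genes`.
    Same sequence -> cis, with distance 0 inside the gene and distance to
    the nearest gene boundary otherwise; different sequence -> trans with
    undefined distance.  Targets absent from the annotation are labelled
    ``unclassified`` (and logged by the caller's summary).
    """
    gi = genes.set_index("gene_id")
    cls, dist = [], []
    for row in eqtl.itertuples(index=False):
        if row.target not in gi.index:
            cls.append("unclassified")
            dist.append(np.nan)
            continue
        g = gi.loc[row.target]
        if g["chrom"] != row.chrom:
            cls.append("trans")
            dist.append(np.nan)
        else:
            cls.append("cis")
            if g["start"] <= row.pos <= g["end"]:
                dist.append(0)
            else:
                dist.append(min(abs(row.pos - g["start"]), abs(row.pos - g["end"])))
    out = eqtl.copy()
    out["classification"] = cls
    out["distance_bp"] = dist
    return out


# ---------------------------------------------------------------------------
# hotspots

@dataclass
class HotspotSummary:
    """Per-SNP and per-mRNA association counts for one tissue's catalog.

    ``per_snp`` maps site_id -> number of distinct target mRNAs (hotspot
    when >= 2); ``per_mrna`` maps mRNA -> number of distinct eQTL SNPs.
    """

    per_snp: pd.Series = field(repr=False)
    per_mrna: pd.Series = field(repr=False)
    hotspots: list = field(default_factory=list)
    snp_mean: float = np.nan
    snp_sd: float = np.nan
    snp_max: int = 0
    mrna_mean: float = np.nan
    mrna_sd: float = np.nan
    mrna_max: int = 0


def find_hotspots(eqtl: pd.DataFrame) -> HotspotSummary:
    """Count targets per SNP and eQTL per mRNA; flag multi-target SNPs.

    ``eqtl`` is one tissue's single-mRNA catalog with ``site_id, target``.
    A hotspot is a SNP associated with >= 2 distinct mRNAs.
    """
    if eqtl.empty:
        empty = pd.Series(dtype=int)
        return HotspotSummary(per_snp=empty, per_mrna=empty)
    per_snp = eqtl.groupby("site_id")["target"].nunique().sort_values(ascending=False)
    per_mrna = eqtl.groupby("target")["site_id"].nunique().sort_values(ascending=False)
    return HotspotSummary(
        per_snp=per_snp,
        per_mrna=per_mrna,
        hotspots=list(per_snp.index[per_snp >= 2]),
        snp_mean=float(per_snp.mean()),
        snp_sd=float(per_snp.std(ddof=1)) if len(per_snp) > 1 else 0.0,
        snp_max=int(per_snp.max()),
        mrna_mean=float(per_mrna.mean()),
        mrna_sd=float(per_mrna.std(ddof=1)) if len(per_mrna) > 1 else 0.0,
        mrna_max=int(per_mrna.max()),
    )


# ---------------------------------------------------------------------------
# chromosome-aware trans null

@dataclass(frozen=True)
class TransTestResult:
    """Observed vs expected cis/trans counts under random placement."""

    chi2: float
    p: float
    n: int
    obs_trans: int
    exp_trans: float
    obs_cis: int
    exp_cis: float
    low_count: bool = False  # expected cell < 5: chi-square approx shaky
    undefined: bool = False


def expected_trans_test(
    classified: pd.DataFrame,
    site_counts: pd.Series,
    genes: pd.DataFrame | None = None,
) -> TransTestResult:
    """Goodness-of-fit test of the trans fraction against site geography.

    For each classified eQTL whose target gene sits on sequence s, the
    null probability of being trans is ``1 - site_counts[s] / total``
    (``site_counts``: tested sites per sequence).  Expected cis/trans
    counts are the sums of those probabilities; the statistic is the
    1-df chi-square over the two cells.  ``genes`` supplies target
    locations when ``classified`` lacks a ``target_chrom`` column.
    Returns ``undefined=True`` when the expected cis count is zero.
    """
    df = classified[classified["classification"].isin(["cis", "trans"])]
    if df.empty:
        raise ValueError("no classified eQTL to test")
    if "target_chrom" in df.columns:
        tchrom = df["target_chrom"]
    else:
        if genes is None:
            raise ValueError("need `genes` or a target_chrom column")
        tchrom = df["target"].map(genes.set_index("gene_id")["chrom"])
    total = float(site_counts.sum())
    p_cis = tchrom.map(site_counts).fillna(0).astype(float) / total
    exp_cis = float(p_cis.sum())
    exp_trans = float((1.0 - p_cis).sum())
    obs_trans = int((df["classification"] == "trans").sum())
    obs_cis = int((df["classification"] == "cis").sum())
    n = obs_cis + obs_trans
    if exp_cis <= 0:
        return TransTestResult(
            chi2=np.nan, p=np.nan, n=n, obs_trans=obs_trans, exp_trans=exp_trans,
            obs_cis=obs_cis, exp_cis=exp_cis, undefined=True,
        )
    chi2 = (obs_cis - exp_cis) ** 2 / exp_cis + (obs_trans - exp_trans) ** 2 / exp_trans
    return TransTestResult(
        chi2=float(chi2), p=float(stats.chi2.sf(chi2, df=1)), n=n,
        obs_trans=obs_trans, exp_trans=exp_trans, obs_cis=obs_cis, exp_cis=exp_cis,
        low_count=min(exp_cis, exp_trans) < 5,
    )


# ---------------------------------------------------------------------------
# proximity annotation

def annotate_proximity(
    snps: pd.DataFrame, genes: pd.DataFrame, window: int = 5000
) -> pd.DataFrame:
    """Genic/intergenic annotation plus transcription-factor proximity.

    A SNP is ``genic`` when it falls inside any gene interval (all
    overlapping genes are reported in ``gene_ids``); ``near_tf`` is true
    when any TF gene lies within ``window`` bp (inclusive) or contains
    the SNP.  ``snps`` needs ``chrom, pos``.
    """
    ann, gids, near = [], [], []
    by_chrom = dict(tuple(genes.groupby("chrom")))
    for row in snps.itertuples(index=False):
        g = by_chrom.get(row.chrom)
        if g is None:
            ann.append("intergenic")
            gids.append("")
            near.append(False)
            continue
        inside = g[(g["start"] <= row.pos) & (row.pos <= g["end"])]
        ann.append("genic" if len(inside) else "intergenic")
        gids.append(",".join(inside["gene_id"]))
        tf = g[g["is_tf"]]
        dist = np.maximum(
            0, np.maximum(tf["start"] - row.pos, row.pos - tf["end"])
        )
        near.append(bool((dist <= window).any()))
    out = snps.copy()
    out["annotation"] = ann
    out["gene_ids"] = gids
    out["near_tf"] = near
    return out


def me_overlap_check(
    me_hits: pd.DataFrame,
    modules: pd.Series,
    genes: pd.DataFrame,
    window: int = 5000,
) -> pd.Series:
    """Is each eigengene eQTL within ``window`` bp of a module member gene?

    ``me_hits`` needs ``chrom, pos, target`` (target = module id);
    ``modules`` maps mRNA/gene id -> module.  True means the SNP lies
    inside or within ``window`` bp of a gene whose mRNA belongs to the
    associated module — i.e. the eigengene association could be a
    disguised cis effect.
    """
    gi = genes.set_index("gene_id")
    flags = []
    for row in me_hits.itertuples(index=False):
        members = modules.index[modules == row.target]
        members = [m for m in members if m in gi.index]
        if not members:
            flags.append(False)
            continue
        sub = gi.loc[members]
        same = sub[sub["chrom"] == row.chrom]
        if same.empty:
            flags.append(False)
            continue
        dist = np.maximum(
            0, np.maximum(same["start"] - row.pos, row.pos - same["end"])
        )
        flags.append(bool((dist <= window).any()))
    return pd.Series(flags, index=me_hits.index, name="near_module_member")


# ---------------------------------------------------------------------------
# shared-eQTL patterns

@dataclass(frozen=True)
class SharingTestResult:
    """Within- vs among-module eQTL sharing over mRNA pairs.

    The unit is the unordered pair of tested mRNAs; the indicator is 1
    when their eQTL site sets intersect.  ``status`` is ``"ok"`` when the
    Welch t-test is defined, ``"degenerate"`` when either group lacks
    variation or pairs (means still reported).
    """

    t: float
    p: float
    within_mean: float
    among_mean: float
    n_within: int
    n_among: int
    status: str = "ok"


def sharing_test(
    eqtl: pd.DataFrame, modules: pd.Series, tested_mrnas: list
) -> SharingTestResult:
    """Welch t-test of eQTL sharing for within- vs among-module mRNA pairs.

    ``eqtl`` is one tissue's single-mRNA catalog (``site_id, target``);
    ``tested_mrnas`` lists every mRNA that entered association testing
    (mRNAs with no significant eQTL share with nobody but still count).
    """
    tested = [str(m) for m in tested_mrnas]
    if len(tested) < 2:
        raise ValueError("need >= 2 tested mRNAs")
    mods = modules.reindex(tested)
    if mods.nunique() < 2:
        raise ValueError("need tested mRNAs in >= 2 modules")
    sets = {m: set() for m in tested}
    for row in eqtl.itertuples(index=False):
        if str(row.target) in sets:
            sets[str(row.target)].add(row.site_id)
    # incidence matrix over the union of sites -> pairwise sharing
    all_sites = sorted(set().union(*sets.values())) if any(sets.values()) else []
    k = len(tested)
    if all_sites:
        site_pos = {s: i for i, s in enumerate(all_sites)}
        A = np.zeros((k, len(all_sites)), dtype=bool)
        for i, m in enumerate(tested):
            for s in sets[m]:
                A[i, site_pos[s]] = True
        share = (A @ A.T.astype(int)) > 0
    else:
        share = np.zeros((k, k), dtype=bool)
    mod_arr = mods.to_numpy()
    iu = np.triu_indices(k, 1)
    same_mod = (mod_arr[iu[0]] == mod_arr[iu[1]]) & ~pd.isna(mod_arr[iu[0]])
    ind = share[iu].astype(float)
    within = ind[same_mod]
    among = ind[~same_mod]
    w_mean = float(within.mean()) if len(within) else np.nan
    a_mean = float(among.mean()) if len(among) else np.nan
    if len(within) < 2 or len(among) < 2:
        return SharingTestResult(np.nan, np.nan, w_mean, a_mean,
                                 len(within), len(among), status="degenerate")
    if within.std() == 0 and among.std() == 0:
        return SharingTestResult(np.nan, np.nan, w_mean, a_mean,
                                 len(within), len(among), status="degenerate")
    t, p = stats.ttest_ind(within, among, equal_var=False)
    return SharingTestResult(float(t), float(p), w_mean, a_mean, len(within), len(among))


# ---------------------------------------------------------------------------
# heterozygosity comparison

@dataclass(frozen=True)
class HeComparisonResult:
    """Mean +/- sd expected heterozygosity of a focal SNP set vs background."""

    focal_mean: float
    focal_sd: float
    background_mean: float
    background_sd: float
    n_focal: int
    n_background: int
    t: float
    p_t: float
    p_perm: float | None = None
    t_defined: bool = True


def he_comparison(
    focal_he,
    background_he,
    n_perm: int = 0,
    rng: np.random.Generator | None = None,
) -> HeComparisonResult:
    """Compare expected heterozygosity between SNP sets.

    Reports mean +/- sd per set with a two-sided Welch t-test; with
    ``n_perm`` > 0 also a permutation p (|focal|-sized resamples from the
    background, two-sided on the mean difference) — robust when the focal
    set is tiny.  The t-test is flagged undefined for |focal| < 2.
    """
    f = np.asarray(focal_he, dtype=float)
    b = np.asarray(background_he, dtype=float)
    if f.size == 0 or b.size == 0:
        raise ValueError("both SNP sets must be non-empty")
    t_defined = f.size >= 2 and b.size >= 2
    if t_defined:
        t, p_t = stats.ttest_ind(f, b, equal_var=False)
        t, p_t = float(t), float(p_t)
    else:
        t, p_t = np.nan, np.nan
    p_perm = None
    if n_perm > 0:
        rng = rng or np.random.default_rng()
        obs = f.mean() - b.mean()
        draws = rng.choice(b, size=(n_perm, f.size), replace=True).mean(axis=1) - b.mean()
        p_perm = float((np.abs(draws) >= abs(obs)).mean())
    return HeComparisonResult(
        focal_mean=float(f.mean()), focal_sd=float(f.std(ddof=1)) if f.size > 1 else 0.0,
        background_mean=float(b.mean()),
        background_sd=float(b.std(ddof=1)) if b.size > 1 else 0.0,
        n_focal=int(f.size), n_background=int(b.size),
        t=t, p_t=p_t, p_perm=p_perm, t_defined=t_defined,
    )


# ---------------------------------------------------------------------------
# overlap sets

def overlap_sets(catalogs: dict) -> pd.DataFrame:
    """Pairwise intersections between named SNP (or gene) sets.

    ``catalogs`` maps a catalog name (e.g. ``trait``, ``heart_eqtl``,
    ``brain_eqtl_me``) to a set of identifiers.  Returns one row per
    unordered pair with the intersection size and members.
    """
    names = list(catalogs)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            inter = sorted(set(catalogs[a]) & set(catalogs[b]))
            rows.append(dict(set_a=a, set_b=b, n_overlap=len(inter),
                             members=",".join(str(x) for x in inter)))
    return pd.DataFrame(rows, columns=["set_a", "set_b", "n_overlap", "members"])


def eqtl_me_consistency(
    eqtl: pd.DataFrame, me_hits: pd.DataFrame, modules: pd.Series
) -> pd.DataFrame:
    """SNPs that are both an eQTL for an mRNA and an eigengene eQTL for
    that same mRNA's module.

    An empty result means eigengene associations are not explained by any
    single high-ranking member mRNA.  ``eqtl`` needs ``site_id, target``
    (mRNA); ``me_hits`` needs ``site_id, target`` (module).
    """
    me_by_site: dict = {}
    for row in me_hits.itertuples(index=False):
        me_by_site.setdefault(row.site_id, set()).add(str(row.target))
    rows = []
    for row in eqtl.itertuples(index=False):
        mod = modules.get(str(row.target))
        if mod is not None and str(mod) in me_by_site.get(row.site_id, set()):
            rows.append(dict(site_id=row.site_id, mrna=row.target, module=mod))
    return pd.DataFrame(rows, columns=["site_id", "mrna", "module"])


# ---------------------------------------------------------------------------
# summary

def architecture_summary(
    classified: pd.DataFrame,
    hotspot: HotspotSummary,
    trans_test: TransTestResult | None = None,
    sharing: SharingTestResult | None = None,
    he: HeComparisonResult | None = None,
) -> dict:
    """Assemble the JSON-ready architecture summary for one tissue.

    Every number is recomputable from the classified catalog and the
    component results — no hidden state.
    """
    sub = classified[classified["classification"].isin(["cis", "trans"])]
    n_cls = len(sub)
    n_trans = int((sub["classification"] == "trans").sum())
    out = {
        "n_eqtl": int(len(classified)),
        "n_classified": n_cls,
        "n_cis": n_cls - n_trans,
        "n_trans": n_trans,
        "trans_fraction": (n_trans / n_cls) if n_cls else np.nan,
        "n_hotspots": len(hotspot.hotspots),
        "per_snp_mrna_count": {
            "mean": hotspot.snp_mean, "sd": hotspot.snp_sd, "max": hotspot.snp_max,
        },
        "per_mrna_eqtl_count": {
            "mean": hotspot.mrna_mean, "sd": hotspot.mrna_sd, "max": hotspot.mrna_max,
        },
    }
    if trans_test is not None:
        out["expected_trans_test"] = {
            "chi2": trans_test.chi2, "p": trans_test.p,
            "obs_trans": trans_test.obs_trans, "exp_trans": trans_test.exp_trans,
            "low_count": trans_test.low_count, "undefined": trans_test.undefined,
        }
    if sharing is not None:
        out["sharing_test"] = {
            "t": sharing.t, "p": sharing.p, "within_mean": sharing.within_mean,
            "among_mean": sharing.among_mean, "status": sharing.status,
        }
    if he is not None:
        out["he_comparison"] = {
            "focal_mean": he.focal_mean, "focal_sd": he.focal_sd,
            "background_mean": he.background_mean, "background_sd": he.background_sd,
            "p_t": he.p_t, "p_perm": he.p_perm,
        }
    return out
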