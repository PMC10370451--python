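"""Score-test association of genotype-likelihood sites with phenotypes.

The test regresses each phenotype on covariates only (the null model) and
scores the addition of the site's expected genotype dosage: with residuals
r from y ~ X, residual dosage d~ (d minus its projection onto X),
sigma^2 = RSS/n,

    U = d~' r / sigma^2,   V = d~' d~ / sigma^2,   T = U^2 / V,

and p is the upper tail of chi-square with 1 df.  With certain genotypes
this is the classical score statistic for adding the dosage to the null
regression; with uncertain genotypes the dosage form is the standard
low-coverage approximation, whose calibration at ~4x depth is verified
empirically in the test suite rather than assumed.

Phenotype families (physiological traits, single mRNAs, module
eigengenes) are corrected separately by Benjamini-Hochberg, and
significant hits within 500 bp of a stronger hit for the same phenotype
are pruned as linked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import coexpr
from .genolik import SiteGL, allele_freq_em_batch, posterior_batch, stack_logliks
from .io import PhenotypeTable, PipelineConfig

logger = logging.getLogger(__name__)

__all__ = [
    "ScoreTestResult",
    "FilterStatus",
    "score_test",
    "apply_site_filters",
    "bh_adjust",
    "prune_hits",
    "run_association_suite",
    "SuiteResult",
]

STATUS_TESTED = "tested"
STATUS_UNTESTABLE = "untestable"
STATUS_MINCOUNT = "minCount_fail"
STATUS_MINHIGH = "minHigh_fail"
STATUS_SMALL_N = "n_too_small"


@dataclass(frozen=True)
class ScoreTestResult:
    """One site x phenotype score test: statistic, p, sample size, status."""

    T: float
    p: float
    n: int
    status: str = STATUS_TESTED


def _design(n: int, covariates: np.ndarray | None) -> np.ndarray:
    X = np.ones((n, 1))
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        X = np.hstack([X, C])
    return X


def score_test(dosages, y, covariates=None) -> ScoreTestResult:
    """Score test of one site's expected dosages against one phenotype.

    ``covariates`` (n x k, no intercept column — one is added) enter the
    null model; individuals with missing phenotype or covariate values are
    dropped.  Returns status ``untestable`` (no statistic) when the
    dosage is collinear with the design — e.g. a monomorphic posterior —
    or when fewer than ``2 + rank(X)`` complete cases remain.
    """
    d = np.asarray(dosages, dtype=float)
    y = np.asarray(y, dtype=float)
    X_full = _design(len(y), covariates)
    ok = np.isfinite(y) & np.isfinite(d) & np.all(np.isfinite(X_full), axis=1)
    d, y, X = d[ok], y[ok], X_full[ok]
    n = int(ok.sum())
    rank = np.linalg.matrix_rank(X) if n else 0
    if n < 2 + rank:
        return ScoreTestResult(T=np.nan, p=np.nan, n=n, status=STATUS_SMALL_N)
    Q, _ = np.linalg.qr(X)
    r = y - Q @ (Q.T @ y)
    rss = float(r @ r)
    d_t = d - Q @ (Q.T @ d)
    dtd = float(d_t @ d_t)
    if dtd <= 1e-12 * max(float(d @ d), 1.0) or rss <= 0:
        return ScoreTestResult(T=np.nan, p=np.nan, n=n, status=STATUS_UNTESTABLE)
    sigma2 = rss / n
    T = float((d_t @ r) ** 2 / (sigma2 * dtd))
    p = float(stats.chi2.sf(T, df=1))
    return ScoreTestResult(T=T, p=max(p, np.nextafter(0, 1)), n=n, status=STATUS_TESTED)


def _score_test_matrix(D: np.ndarray, y: np.ndarray, X: np.ndarray):
    """Vectorized score tests: D (S, n) dosages, shared y (n,) and X (n, k).

    Returns (T, p, testable) arrays; assumes rows of D are finite and the
    caller already subset complete cases.
    """
    n = len(y)
    Q, _ = np.linalg.qr(X)
    r = y - Q @ (Q.T @ y)
    rss = float(r @ r)
    Dt = D - (D @ Q) @ Q.T
    dtd = np.einsum("ij,ij->i", Dt, Dt)
    testable = (dtd > 1e-12 * np.maximum(np.einsum("ij,ij->i", D, D), 1.0)) & (rss > 0)
    sigma2 = rss / n
    with np.errstate(divide="ignore", invalid="ignore"):
        T = (Dt @ r) ** 2 / (sigma2 * dtd)
    T = np.where(testable, T, np.nan)
    p = np.where(testable, stats.chi2.sf(np.nan_to_num(T), df=1), np.nan)
    p = np.where(testable, np.maximum(p, np.nextafter(0, 1)), np.nan)
    return T, p, testable


@dataclass(frozen=True)
class FilterStatus:
    """Per-site association filter outcome.

    ``min_count_ok``: expected minor-allele count >= the threshold.
    ``min_high_ok``: each of the two most populous genotype classes holds
    >= the threshold of high-credibility individuals (max posterior >=
    0.9).  ``status`` collapses the pair to a single label, reporting the
    allele-count failure first when both fail.
    """

    min_count_ok: bool
    min_high_ok: bool

    @property
    def status(self) -> str:
        if not self.min_count_ok:
            return STATUS_MINCOUNT
        if not self.min_high_ok:
            return STATUS_MINHIGH
        return STATUS_TESTED


def apply_site_filters(
    posteriors: np.ndarray,
    dosages: np.ndarray,
    min_high: int = 10,
    min_count: int = 10,
    high_thresh: float = 0.9,
) -> FilterStatus:
    """Association-readiness filters on one site's posteriors/dosages.

    minCount: the expected minor-allele count ``min(sum d, 2n - sum d)``
    must reach ``min_count``.  minHigh: among individuals whose maximum
    genotype posterior is >= ``high_thresh``, the two most populous
    genotype classes must each hold >= ``min_high`` individuals.
    """
    post = np.asarray(posteriors, dtype=float)
    d = np.asarray(dosages, dtype=float)
    n = len(d)
    s = float(d.sum())
    minor = min(s, 2 * n - s)
    count_ok = minor >= min_count
    conf = post.max(axis=1) >= high_thresh
    counts = np.bincount(post[conf].argmax(axis=1), minlength=3) if conf.any() else np.zeros(3, int)
    top2 = np.sort(counts)[::-1][:2]
    high_ok = bool((top2 >= min_high).all())
    return FilterStatus(min_count_ok=bool(count_ok), min_high_ok=high_ok)


def _filters_matrix(post: np.ndarray, dos: np.ndarray, cfg: PipelineConfig):
    """Vectorized filters: post (S, n, 3), dos (S, n) -> status array (S,)."""
    n = dos.shape[1]
    s = dos.sum(axis=1)
    minor = np.minimum(s, 2 * n - s)
    count_ok = minor >= cfg.min_count
    conf = post.max(axis=2) >= cfg.posterior_high
    hard = post.argmax(axis=2)
    counts = np.stack([((hard == g) & conf).sum(axis=1) for g in range(3)], axis=1)
    top2 = np.sort(counts, axis=1)[:, ::-1][:, :2]
    high_ok = (top2 >= cfg.min_high).all(axis=1)
    status = np.full(dos.shape[0], STATUS_TESTED, dtype=object)
    status[~high_ok] = STATUS_MINHIGH
    status[~count_ok] = STATUS_MINCOUNT
    return status


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1).

    Adjustment is meaningful only within one phenotype's family of tested
    sites; callers group accordingly.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def prune_hits(hits: pd.DataFrame, window: int = 500) -> pd.DataFrame:
    """Greedy linkage pruning of one phenotype's significant hits.

    Hits are visited in order of ascending raw p (ties broken by
    (chrom, pos)); a hit is retained iff no already-retained hit on the
    same sequence lies within ``window`` bp.  Each retained hit reports
    how many neighbors it pruned (``pruned_neighbors``).  The result is
    sorted by (chrom, pos) and is invariant to input row order.

    ``hits`` needs columns ``chrom, pos, p_raw``; all columns pass through.
    """
    required = {"chrom", "pos", "p_raw"}
    if not required <= set(hits.columns):
        raise ValueError(f"hits table needs columns {sorted(required)}")
    if hits.empty:
        out = hits.copy()
        out["pruned_neighbors"] = pd.Series(dtype=int)
        return out
    order = hits.sort_values(["p_raw", "chrom", "pos"], kind="stable")
    kept_idx: list = []
    kept_by_chrom: dict = {}
    pruned_count: dict = {}
    for idx, row in order.iterrows():
        chrom, pos = row["chrom"], int(row["pos"])
        blocker = None
        for kidx, kpos in kept_by_chrom.get(chrom, []):
            if abs(pos - kpos) <= window:
                blocker = kidx
                break
        if blocker is None:
            kept_idx.append(idx)
            kept_by_chrom.setdefault(chrom, []).append((idx, pos))
            pruned_count[idx] = 0
        else:
            pruned_count[blocker] += 1
    out = hits.loc[kept_idx].copy()
    out["pruned_neighbors"] = [pruned_count[i] for i in kept_idx]
    return out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# suite driver

CLASS_TRAIT = "trait"
CLASS_MRNA = "single_mRNA"
CLASS_ME = "module_ME"


@dataclass
class SuiteResult:
    """All association tests plus the significant, pruned hit catalog.

    ``tests`` holds one row per (site, phenotype) with the statistic, raw
    and BH-adjusted p and filter status; ``hits`` is the subset with
    adjusted p below the significance level after 500-bp pruning (with
    ``pruned_neighbors`` counts); ``freqs`` carries per-site allele
    frequency, He and effective n; ``module_summaries`` maps tissue ->
    module -> :class:`~lceqtl.coexpr.ModuleSummary`.
    """

    tests: pd.DataFrame
    hits: pd.DataFrame
    freqs: pd.DataFrame
    module_summaries: dict = field(default_factory=dict)

    def hits_for(self, phen_class: str) -> pd.DataFrame:
        return self.hits[self.hits["phen_class"] == phen_class].reset_index(drop=True)


def _phenotype_specs(phenotypes, expression_sets, summaries, cfg):
    """Yield (name, class, tissue, target, values Series, covariate frame).

    ``target`` is the mRNA id for single-mRNA phenotypes and the module id
    for eigengene phenotypes; it is what cis/trans classification and
    module-overlap checks key on downstream.
    """
    specs = []
    if phenotypes is not None:
        cov = phenotypes.covariate_matrix(("temperature", "order"))
        for t in phenotypes.traits:
            specs.append((t, CLASS_TRAIT, "", "", phenotypes.data[t], cov))
    for eset in expression_sets or []:
        tissue = eset.tissue
        cov = None
        if phenotypes is not None:
            cov = phenotypes.covariate_matrix(("temperature",)).reindex(eset.individuals)
        summ = summaries[tissue]
        for module, ms in summ.items():
            for mrna in ms.top:
                specs.append(
                    (f"{tissue}:{mrna}", CLASS_MRNA, tissue, str(mrna), eset.expr[mrna], cov)
                )
            specs.append((f"{tissue}:ME:{module}", CLASS_ME, tissue, str(module), ms.me, cov))
    return specs


def run_association_suite(
    site_gls: list[SiteGL],
    phenotypes: PhenotypeTable | None = None,
    expression_sets=None,
    individuals=None,
    config: PipelineConfig | None = None,
) -> SuiteResult:
    """Run the full association suite: traits, top-k single mRNAs, MEs.

    Covariates follow the study design: acclimation temperature for every
    phenotype, plus acclimation order for physiological traits.  BH
    adjustment is applied within each phenotype's tested sites;
    significance is adjusted p < ``config.fdr_alpha``; significant hits
    are pruned per phenotype with the 500-bp window.

    ``individuals`` names the genotype columns (defaults to Ind0..);
    phenotype/expression tables are aligned to these ids, and phenotypes
    with fewer than ``config.min_complete_cases`` complete cases are
    skipped with a logged reason.
    """
    cfg = config or PipelineConfig()
    ll = stack_logliks(site_gls)
    S, n_ind, _ = ll.shape
    if individuals is None:
        individuals = [f"Ind{i}" for i in range(n_ind)]
    p_hat, n_eff, _ = allele_freq_em_batch(ll)
    post, dos = posterior_batch(ll, np.nan_to_num(p_hat, nan=0.5))
    site_meta = pd.DataFrame(
        {
            "site_id": [g.site.id for g in site_gls],
            "chrom": [g.site.chrom for g in site_gls],
            "pos": [g.site.pos for g in site_gls],
        }
    )
    freqs = site_meta.assign(p=p_hat, he=2 * p_hat * (1 - p_hat), n_eff=n_eff)

    summaries = {}
    for eset in expression_sets or []:
        summaries[eset.tissue] = coexpr.summarize_modules(eset, k=cfg.top_k)

    ind_pos = {ind: i for i, ind in enumerate(individuals)}
    blocks = []
    for name, phen_class, tissue, target, values, cov in _phenotype_specs(
        phenotypes, expression_sets, summaries, cfg
    ):
        values = values[values.index.isin(ind_pos)]
        y = pd.to_numeric(values, errors="coerce")
        if cov is not None:
            cov_sub = cov.reindex(y.index)
            ok = y.notna() & cov_sub.notna().all(axis=1)
        else:
            cov_sub = None
            ok = y.notna()
        ids = list(y.index[ok])
        if len(ids) < cfg.min_complete_cases:
            logger.info(
                "skipping phenotype %r (%s): only %d complete cases", name, phen_class, len(ids)
            )
            continue
        rows = np.array([ind_pos[i] for i in ids])
        yv = y.loc[ids].to_numpy(dtype=float)
        X = _design(len(ids), cov_sub.loc[ids].to_numpy(dtype=float) if cov_sub is not None else None)
        status = _filters_matrix(post[:, rows, :], dos[:, rows], cfg)
        T = np.full(S, np.nan)
        pv = np.full(S, np.nan)
        pass_mask = status == STATUS_TESTED
        if pass_mask.any():
            Tm, pm, testable = _score_test_matrix(dos[np.ix_(pass_mask, rows)], yv, X)
            T[pass_mask], pv[pass_mask] = Tm, pm
            sub = np.nonzero(pass_mask)[0]
            status[sub[~testable]] = STATUS_UNTESTABLE
        block = site_meta.assign(
            phenotype=name,
            phen_class=phen_class,
            tissue=tissue,
            target=target,
            n_used=len(ids),
            T=T,
            p_raw=pv,
            status=status,
        )
        tested = block["status"] == STATUS_TESTED
        padj = np.full(S, np.nan)
        if tested.any():
            padj[tested.to_numpy()] = bh_adjust(block.loc[tested, "p_raw"].to_numpy())
        block["p_adj"] = padj
        blocks.append(block)

    if not blocks:
        tests = site_meta.iloc[0:0].copy()
        return SuiteResult(tests=tests, hits=tests.copy(), freqs=freqs, module_summaries=summaries)
    tests = pd.concat(blocks, ignore_index=True)

    hit_blocks = []
    sig = tests[(tests["status"] == STATUS_TESTED) & (tests["p_adj"] < cfg.fdr_alpha)]
    for _, grp in sig.groupby("phenotype", sort=False):
        hit_blocks.append(prune_hits(grp, window=cfg.prune_window))
    hits = (
        pd.concat(hit_blocks, ignore_index=True)
        if hit_blocks
        else tests.iloc[0:0].assign(pruned_neighbors=pd.Series(dtype=int))
    )
    return SuiteResult(tests=tests, hits=hits, freqs=freqs, module_summaries=summaries)
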