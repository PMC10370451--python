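"""Pairwise linkage disequilibrium from genotype likelihoods.

r^2 between two sites is estimated by an EM over the four two-locus
haplotype frequencies, maximizing the unphased likelihood

    sum_i log sum_{g1,g2} L_i(g1) L_i(g2) P(g1, g2 | f)

where P(g1, g2 | f) sums Hardy-Weinberg diplotype probabilities over the
ordered haplotype pairs compatible with the genotype pair.  At infinite
depth this reduces to the classic genotype-based haplotype EM (Hill's
method) on hard calls.  Decay summaries bin same-sequence pairs by
distance, which motivates the pipeline's 500-bp independence window.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genolik import SiteGL, estimate_allele_freq_em

__all__ = ["LdResult", "MonomorphicSiteError", "pairwise_r2_em", "ld_decay"]


class MonomorphicSiteError(ValueError):
    """r^2 is undefined when either site is monomorphic (p in {0, 1})."""


# The 4 haplotypes are indexed h = 2*a1 + a2 where a1, a2 are the alleles
# (0 = ref, 1 = alt) carried at site 1 and site 2.  Enumerate the 16
# ordered haplotype pairs once, with the genotype pair each implies.
_PAIRS = np.array(list(itertools.product(range(4), repeat=2)))  # (16, 2)
_G1 = (_PAIRS // 2).sum(axis=1)  # alt copies at site 1 per ordered pair
_G2 = (_PAIRS % 2).sum(axis=1)  # alt copies at site 2
_H_COUNT = np.zeros((16, 4))  # haplotype count contributed by each pair
for _k, (_a, _b) in enumerate(_PAIRS):
    _H_COUNT[_k, _a] += 1
    _H_COUNT[_k, _b] += 1


@dataclass(frozen=True)
class LdResult:
    """Two-locus haplotype frequencies and derived LD statistics.

    ``hap_freqs`` orders the haplotypes (ref-ref, ref-alt, alt-ref,
    alt-alt); ``D = f_altalt - p1 * p2`` and ``r2 = D^2 / (p1 (1-p1)
    p2 (1-p2))``.  ``distance`` is bp between the sites, None across
    sequences.
    """

    site1: str
    site2: str
    distance: int | None
    hap_freqs: tuple
    D: float
    r2: float
    p1: float
    p2: float
    n_iter: int = 0

    def __post_init__(self) -> None:
        f = np.asarray(self.hap_freqs)
        if np.any(f < -1e-9) or abs(f.sum() - 1.0) > 1e-6:
            raise ValueError("haplotype frequencies must be >= 0 and sum to 1")
        if not -1e-9 <= self.r2 <= 1 + 1e-9:
            raise ValueError(f"r2 {self.r2} outside [0, 1]")


def pairwise_r2_em(
    site_gl_1: SiteGL,
    site_gl_2: SiteGL,
    tol: float = 1e-6,
    max_iter: int = 500,
    return_trace: bool = False,
):
    """EM estimate of r^2 between two sites over the same individuals.

    Starts at linkage equilibrium (products of the single-site ML
    frequencies) and ascends the unphased two-locus likelihood; the
    likelihood trace is non-decreasing and can be returned for
    verification.  Raises :class:`MonomorphicSiteError` when either
    site's marginal frequency is at a boundary, where r^2 is undefined.
    """
    if site_gl_1.n_individuals != site_gl_2.n_individuals:
        raise ValueError("sites cover different individual sets")
    e1 = estimate_allele_freq_em(site_gl_1)
    e2 = estimate_allele_freq_em(site_gl_2)
    eps = 1e-9
    if min(e1.p, 1 - e1.p) <= eps or min(e2.p, 1 - e2.p) <= eps:
        raise MonomorphicSiteError(
            f"monomorphic site ({site_gl_1.site.id}: p={e1.p:.3g}, "
            f"{site_gl_2.site.id}: p={e2.p:.3g})"
        )
    L1 = site_gl_1.likelihoods()  # (n, 3)
    L2 = site_gl_2.likelihoods()
    # per-individual likelihood of each ordered haplotype pair's genotypes
    pair_lik = L1[:, _G1] * L2[:, _G2]  # (n, 16)
    n = pair_lik.shape[0]
    # linkage-equilibrium start
    m1 = np.array([1 - e1.p, e1.p])
    m2 = np.array([1 - e2.p, e2.p])
    f = np.outer(m1, m2).ravel()  # f[2*a1 + a2]
    trace: list[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        w = pair_lik * (f[_PAIRS[:, 0]] * f[_PAIRS[:, 1]])  # (n, 16)
        tot = np.maximum(w.sum(axis=1), 1e-300)  # (n,)
        trace.append(float(np.log(tot).sum()))
        resp = w / tot[:, None]
        counts = resp @ _H_COUNT  # (n, 4) expected haplotype counts
        f_new = counts.sum(axis=0) / (2.0 * n)
        if np.abs(f_new - f).max() < tol:
            f = f_new
            break
        f = f_new
    f = np.clip(f, 0.0, 1.0)
    f = f / f.sum()
    p1 = f[2] + f[3]
    p2 = f[1] + f[3]
    denom = p1 * (1 - p1) * p2 * (1 - p2)
    if denom <= eps**2:
        raise MonomorphicSiteError(
            f"EM converged to a monomorphic margin (p1={p1:.3g}, p2={p2:.3g})"
        )
    D = f[3] - p1 * p2
    r2 = min(D * D / denom, 1.0)
    s1, s2 = site_gl_1.site, site_gl_2.site
    dist = abs(s1.pos - s2.pos) if s1.chrom == s2.chrom else None
    res = LdResult(
        site1=s1.id, site2=s2.id, distance=dist, hap_freqs=tuple(f),
        D=float(D), r2=float(r2), p1=float(p1), p2=float(p2), n_iter=n_iter,
    )
    if return_trace:
        return res, trace
    return res


def ld_decay(
    site_gls: list[SiteGL],
    max_dist: int = 1000,
    bin_width: int = 100,
    tol: float = 1e-6,
    max_iter: int = 500,
):
    """Mean r^2 by distance bin over all same-sequence pairs within range.

    Pairs on different sequences are excluded (distance undefined);
    monomorphic pairs are skipped.  Bins with no pairs are reported with
    ``n_pairs = 0`` and NaN mean (empty, not zero).

    Returns ``(per_bin, per_pair)`` DataFrames.
    """
    if bin_width <= 0 or max_dist <= 0:
        raise ValueError("max_dist and bin_width must be positive")
    pairs = []
    by_chrom: dict = {}
    for gl in site_gls:
        by_chrom.setdefault(gl.site.chrom, []).append(gl)
    for chrom_sites in by_chrom.values():
        chrom_sites.sort(key=lambda g: g.site.pos)
        for i, a in enumerate(chrom_sites):
            for b in chrom_sites[i + 1 :]:
                d = b.site.pos - a.site.pos
                if d > max_dist:
                    break
                try:
                    res = pairwise_r2_em(a, b, tol=tol, max_iter=max_iter)
                except MonomorphicSiteError:
                    continue
                pairs.append(
                    dict(site1=res.site1, site2=res.site2, distance=d, r2=res.r2)
                )
    per_pair = pd.DataFrame(pairs, columns=["site1", "site2", "distance", "r2"])
    edges = np.arange(0, max_dist + bin_width, bin_width)
    lo, hi = edges[:-1], edges[1:]
    n_pairs = np.zeros(len(lo), dtype=int)
    mean_r2 = np.full(len(lo), np.nan)
    if len(per_pair):
        which = np.minimum((per_pair["distance"] - 1) // bin_width, len(lo) - 1)
        for b in range(len(lo)):
            sel = per_pair["r2"][which == b]
            n_pairs[b] = len(sel)
            if len(sel):
                mean_r2[b] = float(sel.mean())
    per_bin = pd.DataFrame(
        {"bin_lo": lo, "bin_hi": hi, "n_pairs": n_pairs, "mean_r2": mean_r2}
    )
    return per_bin, per_pair
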