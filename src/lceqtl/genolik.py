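"""Genotype-likelihood numerics.

Low-coverage sequencing does not support confident per-individual genotype
calls, so every downstream computation in this package works from the
per-individual likelihoods ``L_i(g)`` of the three genotypes g = 0, 1, 2
(copies of the alternate allele).  This module provides the shared site
containers plus the three primitives everything else is built on:

* a one-dimensional EM for the maximum-likelihood alternate-allele
  frequency under Hardy-Weinberg,
* Hardy-Weinberg genotype posteriors and expected dosages, and
* expected heterozygosity He = 2 p (1 - p).

An individual with no reads at a site carries a flat (all-equal)
likelihood row; such rows are detected structurally and contribute the
prior alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SiteRecord",
    "SiteGL",
    "FreqEstimate",
    "AllMissingError",
    "estimate_allele_freq_em",
    "allele_freq_em_batch",
    "genotype_posteriors",
    "heterozygosity",
]

_BASES = ("A", "C", "G", "T")


class AllMissingError(ValueError):
    """Raised when an allele frequency is requested for a site where every
    individual has a flat (missing) likelihood row."""


@dataclass(frozen=True)
class SiteRecord:
    """A biallelic variant site.

    Coordinates are 1-based, as in VCF.  ``id`` defaults to
    ``"{chrom}_{pos}"``, the marker naming used by beagle GL files.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt alleles must differ at {self.chrom}:{self.pos}")
        if not self.id:
            object.__setattr__(self, "id", f"{self.chrom}_{self.pos}")


@dataclass
class SiteGL:
    """Per-individual genotype log-likelihoods at one site.

    ``loglik`` has shape (n_individuals, 3) for genotypes 0/1/2 alt copies
    and is max-normalized per individual on construction (each row's
    maximum becomes 0), so values are finite or ``-inf`` and comparable
    across individuals.  A row whose three values are equal marks a
    missing individual.
    """

    site: SiteRecord
    loglik: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        ll = np.asarray(self.loglik, dtype=float)
        if ll.ndim != 2 or ll.shape[1] != 3:
            raise ValueError(f"loglik must have shape (n, 3), got {ll.shape}")
        rowmax = ll.max(axis=1)
        if not np.all(np.isfinite(rowmax)):
            raise ValueError("each individual needs at least one finite log-likelihood")
        self.loglik = ll - rowmax[:, None]

    @property
    def n_individuals(self) -> int:
        return self.loglik.shape[0]

    def missing_mask(self) -> np.ndarray:
        """Boolean mask of individuals with flat (uninformative) rows."""
        return np.ptp(self.loglik, axis=1) == 0

    def likelihoods(self) -> np.ndarray:
        """Linear-scale likelihoods, max-normalized per individual."""
        return np.exp(self.loglik)


@dataclass(frozen=True)
class FreqEstimate:
    """Maximum-likelihood allele frequency summary for one site.

    ``he`` is always exactly ``2 * p * (1 - p)``; ``n_eff`` counts the
    non-missing individuals the estimate is based on.
    """

    p: float
    he: float
    n_eff: int
    n_iter: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"allele frequency {self.p} outside [0, 1]")


def heterozygosity(p):
    """Expected heterozygosity He = 2 p (1 - p).

    Accepts a scalar or array of allele frequencies in [0, 1]; raises
    ``ValueError`` outside that domain.  Symmetric under p <-> 1 - p with
    maximum 0.5 at p = 0.5.
    """
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0.0) | (arr > 1.0)):
        raise ValueError("allele frequency outside [0, 1]")
    he = 2.0 * arr * (1.0 - arr)
    return float(he) if np.isscalar(p) or arr.ndim == 0 else he


def _hwe_prior(p: float | np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    return np.stack([(1.0 - p) ** 2, 2.0 * p * (1.0 - p), p**2], axis=-1)


def allele_freq_em_batch(
    loglik: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 200,
    p0: float = 0.25,
):
    """Vectorized HWE allele-frequency EM over many sites at once.

    Parameters
    ----------
    loglik
        Array (n_sites, n_individuals, 3) of max-normalized genotype
        log-likelihoods.
    tol, max_iter
        Convergence is declared when every site moves by less than ``tol``
        between iterations, or after ``max_iter`` iterations.
    p0
        Common starting frequency.  The per-site likelihood in p is
        unimodal, so the start only affects iteration count.

    Returns
    -------
    (p, n_eff, n_iter)
        Arrays of per-site ML frequencies and non-missing counts, plus the
        number of iterations run.

    Sites where every individual is missing get ``p = nan`` (the per-site
    wrapper turns that into :class:`AllMissingError`).
    """
    lik = np.exp(loglik)  # (S, n, 3)
    miss = np.ptp(loglik, axis=2) == 0  # (S, n)
    obs = ~miss
    n_eff = obs.sum(axis=1)  # (S,)
    S = lik.shape[0]
    p = np.full(S, p0, dtype=float)
    active = n_eff > 0
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        prior = _hwe_prior(p)  # (S, 3)
        w = lik * prior[:, None, :]  # (S, n, 3)
        tot = w.sum(axis=2)  # (S, n)
        # guard individuals with zero posterior mass (degenerate prior at a
        # boundary combined with zero likelihood there): treat as missing
        safe = tot > 0
        dos = np.zeros_like(tot)
        np.divide(w[..., 1] + 2.0 * w[..., 2], tot, out=dos, where=safe)
        use = obs & safe
        denom = 2.0 * use.sum(axis=1)
        p_new = np.where(denom > 0, (dos * use).sum(axis=1) / np.maximum(denom, 1), p)
        delta = np.abs(p_new - p)
        p = p_new
        if not np.any(delta[active] >= tol):
            break
    p = np.where(n_eff > 0, np.clip(p, 0.0, 1.0), np.nan)
    return p, n_eff, n_iter


def estimate_allele_freq_em(
    site_gl: SiteGL,
    tol: float = 1e-6,
    max_iter: int = 200,
    return_trace: bool = False,
):
    """ML alternate-allele frequency for one site by HWE EM.

    The EM ascends the marginal likelihood
    ``sum_i log sum_g L_i(g) HWE(g; p)``; each iteration replaces p with
    the posterior mean dosage over non-missing individuals divided by 2.
    The likelihood is non-decreasing across iterations (returned as a
    trace when ``return_trace`` is set, so callers can assert it).

    Returns a :class:`FreqEstimate`; raises :class:`AllMissingError` when
    no individual carries information.
    """
    miss = site_gl.missing_mask()
    if miss.all():
        raise AllMissingError(f"all individuals missing at {site_gl.site.id}")
    lik = site_gl.likelihoods()[~miss]
    n = lik.shape[0]
    p = 0.25
    trace: list[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        w = lik * _hwe_prior(p)
        tot = w.sum(axis=1)
        trace.append(float(np.log(tot).sum()))
        p_new = float(((w[:, 1] + 2.0 * w[:, 2]) / tot).sum() / (2.0 * n))
        if abs(p_new - p) < tol:
            p = p_new
            break
        p = p_new
    p = min(max(p, 0.0), 1.0)
    est = FreqEstimate(p=p, he=heterozygosity(p), n_eff=int(n), n_iter=n_iter)
    if return_trace:
        return est, trace
    return est


def genotype_posteriors(site_gl: SiteGL, p: float):
    """HWE genotype posteriors and expected dosages at frequency ``p``.

    Missing individuals (flat likelihoods) receive the prior itself.  In
    the rare degenerate case of zero posterior mass (a boundary prior with
    no likelihood support where the prior lives), the prior is returned
    for that individual as well.

    Returns ``(posteriors, dosages)`` with shapes (n, 3) and (n,);
    ``dosage_i = P(g=1) + 2 P(g=2)`` lies in [0, 2].
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"allele frequency {p} outside [0, 1]")
    lik = site_gl.likelihoods()
    prior = _hwe_prior(p)
    num = lik * prior
    tot = num.sum(axis=1)
    post = np.empty_like(num)
    ok = tot > 0
    post[ok] = num[ok] / tot[ok, None]
    post[~ok] = prior
    dosage = post[:, 1] + 2.0 * post[:, 2]
    return post, dosage


def posterior_batch(loglik: np.ndarray, p: np.ndarray):
    """Vectorized posteriors/dosages: (S, n, 3) log-likelihoods + (S,) freqs.

    Returns (posteriors (S, n, 3), dosages (S, n)).  Same conventions as
    :func:`genotype_posteriors`.
    """
    lik = np.exp(loglik)
    prior = _hwe_prior(np.asarray(p, dtype=float))  # (S, 3)
    num = lik * prior[:, None, :]
    tot = num.sum(axis=2)
    post = np.empty_like(num)
    ok = tot > 0
    post[ok] = num[ok] / tot[ok, None]
    bad_s, bad_i = np.nonzero(~ok)
    post[bad_s, bad_i] = prior[bad_s]
    dosage = post[..., 1] + 2.0 * post[..., 2]
    return post, dosage


def stack_logliks(site_gls) -> np.ndarray:
    """Stack a list of :class:`SiteGL` into one (S, n, 3) array.

    Raises ``ValueError`` if individual counts differ between sites.
    """
    counts = {g.n_individuals for g in site_gls}
    if len(counts) > 1:
        raise ValueError(f"inconsistent individual counts across sites: {sorted(counts)}")
    return np.stack([g.loglik for g in site_gls], axis=0)
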