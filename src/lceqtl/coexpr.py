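"""Module-level expression summaries.

Co-expression module *assignments* are an input (they come from an
upstream weighted co-expression network analysis); this module computes
only the quantities the association pipeline consumes:

* the module eigengene (ME) — the first principal component of the
  module's standardized expression, one score per individual, scaled to
  unit variance with the sign fixed so the mean member correlation is
  non-negative;
* module membership (kME) — the Pearson correlation between each member
  mRNA and its module's ME; and
* the top-k member mRNAs per module ranked by kME, which define the
  single-mRNA phenotypes tested for eQTL.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionSet",
    "ModuleSummary",
    "module_eigengene",
    "module_membership",
    "select_top_k",
    "summarize_modules",
]


@dataclass
class ExpressionSet:
    """Expression matrix with gene coordinates and module assignments.

    ``expr`` is individuals x mRNAs (real-valued, NaN = missing);
    ``genes`` has one row per mRNA (``gene_id, chrom, start, end, strand,
    is_tf``); ``modules`` maps mRNA id -> module id.  ``tissue`` labels
    the organ the expression was measured in (e.g. heart or brain);
    catalogs downstream are tissue-specific.
    """

    expr: pd.DataFrame
    genes: pd.DataFrame
    modules: pd.Series
    tissue: str = "tissue"

    def __post_init__(self) -> None:
        missing = set(self.expr.columns) - set(self.modules.index)
        if missing:
            raise ValueError(f"mRNAs without a module assignment: {sorted(missing)[:5]} ...")
        sizes = self.modules.loc[list(self.expr.columns)].value_counts()
        small = sizes[sizes < 2]
        if len(small):
            raise ValueError(f"modules with fewer than 2 mRNAs: {list(small.index)}")

    @property
    def individuals(self) -> list:
        return list(self.expr.index)

    def module_ids(self) -> list:
        return sorted(self.modules.loc[list(self.expr.columns)].unique())

    def module_members(self, module) -> list:
        members = self.modules[self.modules == module].index
        return [m for m in self.expr.columns if m in set(members)]


@dataclass
class ModuleSummary:
    """Eigengene, memberships and the ranked top-k list for one module."""

    module: object
    me: pd.Series = field(repr=False)
    kme: pd.Series = field(repr=False)
    top: list = field(default_factory=list)
    short: bool = False  # module had < k members; `top` is all of them


def _standardize(expr: pd.DataFrame):
    """Mean-impute missing values per mRNA, drop zero-variance columns,
    return the standardized matrix (mean 0, sd 1 per column)."""
    X = expr.to_numpy(dtype=float).copy()
    col_mean = np.nanmean(X, axis=0)
    nan_count = int(np.isnan(X).sum())
    if nan_count:
        logger.info("mean-imputing %d missing expression value(s)", nan_count)
        idx = np.nonzero(np.isnan(X))
        X[idx] = col_mean[idx[1]]
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        logger.warning(
            "dropping %d zero-variance mRNA(s): %s",
            (~keep).sum(), list(expr.columns[~keep])[:5],
        )
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    return Z, list(expr.columns[keep])


def module_eigengene(expr: pd.DataFrame) -> pd.Series:
    """First principal component of a module's expression, per individual.

    Columns are standardized (zero-variance mRNAs dropped with a warning),
    the first right-singular direction's individual scores are taken and
    rescaled to unit variance (ddof=1), and the sign is flipped if the
    mean correlation with member mRNAs is negative — making the result
    deterministic and invariant to mRNA ordering.

    Requires >= 2 usable mRNAs and >= 3 individuals.
    """
    if expr.shape[0] < 3:
        raise ValueError(f"eigengene needs >= 3 individuals, got {expr.shape[0]}")
    Z, kept = _standardize(expr)
    if len(kept) < 2:
        raise ValueError("fewer than 2 mRNAs with nonzero variance")
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    scores = U[:, 0] * s[0]
    sd = scores.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate module: first principal component has zero variance")
    scores = scores / sd
    me = pd.Series(scores, index=expr.index, name="ME")
    if module_membership(expr[kept], me).mean() < 0:
        me = -me
    return me


def module_membership(expr: pd.DataFrame, me: pd.Series) -> pd.Series:
    """kME: Pearson correlation of each mRNA with the module eigengene.

    Zero-variance mRNAs get NaN (undefined, reported missing).  Missing
    expression values are mean-imputed to match the eigengene computation.
    """
    X = expr.to_numpy(dtype=float).copy()
    col_mean = np.nanmean(X, axis=0)
    idx = np.nonzero(np.isnan(X))
    X[idx] = col_mean[idx[1]]
    m = me.loc[expr.index].to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    mc = m - m.mean()
    denom = np.sqrt((Xc**2).sum(axis=0) * (mc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, Xc.T @ mc / np.where(denom > 0, denom, 1.0), np.nan)
    return pd.Series(np.clip(r, -1.0, 1.0), index=expr.columns, name="kME")


def select_top_k(kme: pd.Series, k: int = 10):
    """The k mRNAs with highest kME, ties broken by mRNA id.

    Returns ``(ids, short)`` where ``short`` flags a module with fewer
    than k scored members (all of them are returned).
    """
    scored = kme.dropna()
    order = sorted(scored.index, key=lambda g: (-scored[g], str(g)))
    short = len(order) < k
    return order[:k], short


def summarize_modules(eset: ExpressionSet, k: int = 10) -> dict:
    """Compute :class:`ModuleSummary` for every module of an expression set."""
    out = {}
    for module in eset.module_ids():
        members = eset.module_members(module)
        sub = eset.expr[members]
        me = module_eigengene(sub)
        kme = module_membership(sub, me)
        top, short = select_top_k(kme, k=k)
        out[module] = ModuleSummary(module=module, me=me, kme=kme, top=top, short=short)
    return out
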