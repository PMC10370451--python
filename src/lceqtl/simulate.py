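"""Synthetic low-coverage genotype + expression + trait generator.

Emulates the statistical structure the pipeline assumes, so the whole
analysis runs end to end with no external data:

* a genome of 24 large chromosomes plus small scaffolds (scaffolds carry
  ~21.6% of the total length),
* Hardy-Weinberg genotypes at sites with minor allele frequency drawn
  from Uniform(0.05, 0.5), positions uniform over the genome,
* read-level genotype likelihoods under Poisson coverage (default 4.1x)
  with a symmetric base-error rate,
* module-structured expression: each co-expression module has a latent
  factor; planted *trans* eQTL add a genotype effect to the factor itself
  (so hotspots arise mechanistically — one SNP moves many co-expressed
  mRNAs), while planted *cis* eQTL add a genotype effect to a single gene
  located on the same sequence as its SNP; module member genes are placed
  on sequences other than their module's planted SNPs, so trans labels
  are generative truth;
* traits driven by module factors plus acclimation-temperature and
  acclimation-order covariates, observed for a small phenotyped subset.

Everything is drawn from one seeded ``numpy.random.Generator`` stream, so
a fixed seed reproduces the dataset exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .coexpr import ExpressionSet
from .genolik import SiteGL, SiteRecord
from .io import GenomeLayout, PhenotypeTable

__all__ = [
    "SimConfig",
    "TruthSet",
    "SimulatedData",
    "default_layout",
    "simulate_genotypes",
    "simulate_gls",
    "simulate_expression",
    "simulate_traits",
    "simulate_dataset",
    "write_dataset",
]


def default_layout(
    n_chrom: int = 24,
    chrom_length: int = 30_000_000,
    n_scaffolds: int = 50,
    scaffold_fraction: float = 0.216,
) -> GenomeLayout:
    """A genome of equal large chromosomes plus small scaffolds.

    Scaffold lengths are set so that scaffolds carry ``scaffold_fraction``
    of the total assembly (chromosomes the rest), mirroring an assembly
    where ~78% of sequence sits on 24 chromosomes each >28 Mb.
    """
    chrom_total = n_chrom * chrom_length
    scaf_total = chrom_total * scaffold_fraction / (1.0 - scaffold_fraction)
    scaf_len = max(int(scaf_total / max(n_scaffolds, 1)), 1)
    names = [f"chr{i + 1}" for i in range(n_chrom)] + [
        f"scaf{i + 1}" for i in range(n_scaffolds)
    ]
    lengths = [chrom_length] * n_chrom + [scaf_len] * n_scaffolds
    classes = ["chromosome"] * n_chrom + ["scaffold"] * n_scaffolds
    return GenomeLayout(names, lengths, classes)


@dataclass
class SimConfig:
    """All generator knobs, defaulting to the emulated study's conditions.

    172 genotyped individuals sequenced at mean 4.1x Poisson coverage
    with base-error 0.01; ~25 of them expression-profiled and trait
    phenotyped; sites at MAF ~ Uniform(0.05, 0.5) spread uniformly over a
    24-chromosome + 50-scaffold layout.  Desk-scale structural choices
    (site and module counts, loadings, effect sizes) are documented in
    the methods note.
    """

    n_individuals: int = 172
    n_pheno: int = 25
    n_expr: int = 25
    n_sites: int = 5000
    layout: GenomeLayout | None = None
    mean_depth: float = 4.1
    base_error: float = 0.01
    maf_range: tuple = (0.05, 0.5)
    n_modules: int = 10
    genes_per_module: int = 30
    loading: float = 0.8
    expr_noise_sd: float = 0.6
    n_trans_eqtl: int = 20
    n_cis_eqtl: int = 2
    eqtl_beta: float = 1.0
    expr_temp_effect: float = 0.5
    n_traits: int = 6
    trait_module_weight: float = 1.0
    trait_temp_effect: float = 0.5
    trait_order_effect: float = 0.25
    trait_noise_sd: float = 0.5
    tf_fraction: float = 0.08
    tissue: str = "heart"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.layout is None:
            self.layout = default_layout()
        for name in (
            "n_individuals", "n_pheno", "n_expr", "n_sites",
            "n_modules", "genes_per_module", "n_traits",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 < self.base_error < 0.5:
            raise ValueError("base_error must lie in (0, 0.5)")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be >= 0")
        if self.n_pheno > self.n_individuals or self.n_expr > self.n_individuals:
            raise ValueError("phenotyped/expressed subsets cannot exceed n_individuals")
        for name in ("eqtl_beta", "loading", "trait_module_weight"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass
class TruthSet:
    """Generative ground truth for parameter-recovery checks.

    ``planted`` has one row per planted eQTL: ``site_id, chrom, pos,
    target, target_type (gene | module), module, beta, label (cis |
    trans)``.  A cis label always means the site shares the target
    gene's sequence; module-factor eQTL are trans with respect to every
    member gene by construction.
    """

    genotypes: np.ndarray = field(repr=False)  # (S, n) 0/1/2
    maf: np.ndarray = field(repr=False)
    planted: pd.DataFrame = field(repr=False)
    factors: pd.DataFrame = field(repr=False)  # individuals x modules
    trait_weights: pd.DataFrame = field(repr=False)

    def validate(self, sites, genes: pd.DataFrame) -> None:
        site_ids = {s.id for s in sites}
        gene_ids = set(genes["gene_id"])
        gene_chrom = genes.set_index("gene_id")["chrom"]
        for row in self.planted.itertuples(index=False):
            if row.site_id not in site_ids:
                raise ValueError(f"planted eQTL references unknown site {row.site_id}")
            if row.target_type == "gene":
                if row.target not in gene_ids:
                    raise ValueError(f"planted eQTL references unknown gene {row.target}")
                same = gene_chrom[row.target] == row.chrom
                if (row.label == "cis") != same:
                    raise ValueError(
                        f"label {row.label} inconsistent with sequences for {row.site_id}"
                    )


@dataclass
class SimulatedData:
    """Bundle of everything one simulated study produces."""

    config: SimConfig
    layout: GenomeLayout
    sites: list
    site_gls: list = field(repr=False)
    individuals: list = field(repr=False)
    expression: ExpressionSet = field(repr=False)
    phenotypes: PhenotypeTable = field(repr=False)
    truth: TruthSet = field(repr=False)


# ---------------------------------------------------------------------------
# genotypes and likelihoods

def simulate_genotypes(config: SimConfig, rng: np.random.Generator):
    """Hardy-Weinberg genotypes at uniformly placed biallelic sites.

    Returns ``(genotypes (S, n) int8, sites list[SiteRecord], maf (S,))``;
    sites are sorted by layout order then position, with unique
    (chrom, pos).
    """
    layout = config.layout
    lengths = np.asarray(layout.lengths, dtype=float)
    weights = lengths / lengths.sum()
    S = config.n_sites
    seq_idx = rng.choice(len(lengths), size=S, p=weights)
    pos = rng.integers(1, np.asarray(layout.lengths)[seq_idx] + 1)
    # ensure unique (chrom, pos)
    seen = set(zip(seq_idx.tolist(), pos.tolist()))
    while len(seen) < S:
        k = S - len(seen)
        extra_seq = rng.choice(len(lengths), size=k, p=weights)
        extra_pos = rng.integers(1, np.asarray(layout.lengths)[extra_seq] + 1)
        seen.update(zip(extra_seq.tolist(), extra_pos.tolist()))
    coords = sorted(seen)[:S]
    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=S)
    bases = np.array(["A", "C", "G", "T"])
    ref_i = rng.integers(0, 4, size=S)
    alt_i = (ref_i + rng.integers(1, 4, size=S)) % 4
    sites = [
        SiteRecord(
            chrom=layout.names[si], pos=int(p), ref=str(bases[ref_i[k]]), alt=str(bases[alt_i[k]])
        )
        for k, (si, p) in enumerate(coords)
    ]
    genotypes = rng.binomial(2, maf[:, None], size=(S, config.n_individuals)).astype(np.int8)
    return genotypes, sites, maf


def simulate_gls(
    genotypes: np.ndarray,
    sites: list,
    mean_depth: float,
    base_error: float,
    rng: np.random.Generator,
) -> list[SiteGL]:
    """Read-sampling genotype likelihoods at Poisson coverage.

    Per individual and site: read count m ~ Poisson(depth); alternate
    reads ~ Binomial(m, e_g) with e_g = (g/2)(1-eps) + (1-g/2)eps; the
    three genotype log-likelihoods use the same binomial model (the
    combinatorial factor cancels in normalization).  Zero reads gives a
    flat, uninformative row.
    """
    G = np.asarray(genotypes)
    S, n = G.shape
    depth = rng.poisson(mean_depth, size=(S, n))
    e_true = (G / 2.0) * (1 - base_error) + (1 - G / 2.0) * base_error
    alt_reads = rng.binomial(depth, e_true)
    ref_reads = depth - alt_reads
    e_g = np.array([base_error, 0.5, 1 - base_error])  # P(alt read | g)
    with np.errstate(divide="ignore"):
        ll = (
            alt_reads[..., None] * np.log(e_g)
            + ref_reads[..., None] * np.log(1 - e_g)
        )
    return [SiteGL(site=sites[s], loglik=ll[s]) for s in range(S)]


# ---------------------------------------------------------------------------
# expression

def _place_gene(rng, layout, allowed_idx, min_len=1000, max_len=20000):
    lengths = np.asarray(layout.lengths, dtype=float)
    w = lengths[allowed_idx] / lengths[allowed_idx].sum()
    si = int(rng.choice(allowed_idx, p=w))
    L = int(layout.lengths[si])
    glen = int(rng.integers(min_len, min(max_len, L) + 1))
    start = int(rng.integers(1, max(L - glen, 1) + 1))
    return si, start, min(start + glen - 1, L)


def simulate_expression(
    config: SimConfig,
    genotypes: np.ndarray,
    sites: list,
    maf: np.ndarray,
    rng: np.random.Generator,
    temperature: np.ndarray | None = None,
):
    """Module-structured expression with planted cis and trans eQTL.

    Each module m has a latent factor ``f_m = N(0,1) + sum beta (g -
    2*maf) [+ temp shift]`` over the planted module-level (trans) SNPs;
    member gene expression is ``x = loading * f_m + N(0, sd)``, plus
    ``beta (g - 2*maf)`` for the cis-planted genes.  Member genes are
    placed on sequences other than their module's planted SNPs (trans
    truth); each cis target shares its SNP's sequence.

    Returns ``(ExpressionSet, factors DataFrame, planted DataFrame,
    genes DataFrame)``.  Expression is profiled for the subset of
    individuals chosen in :func:`simulate_dataset`; here the full matrix
    is produced and subset later.
    """
    S, n = np.asarray(genotypes).shape
    layout = config.layout
    n_seq = len(layout.names)
    site_seq = {s.id: layout.names.index(s.chrom) for s in sites}
    M, gpm = config.n_modules, config.genes_per_module

    # --- plant module-level (trans) eQTL, round-robin over modules
    chosen = rng.choice(S, size=min(config.n_trans_eqtl + config.n_cis_eqtl, S), replace=False)
    trans_sites = chosen[: config.n_trans_eqtl]
    cis_sites = chosen[config.n_trans_eqtl :]
    module_of_trans = [k % M for k in range(len(trans_sites))]

    if temperature is None:
        temp_std = np.zeros(n)
    else:
        temp_std = (np.asarray(temperature, dtype=float) - 20.0) / 8.0  # 12/28 -> -1/+1

    centered = np.asarray(genotypes, dtype=float) - 2.0 * maf[:, None]
    factors = rng.standard_normal((n, M))
    factors += config.expr_temp_effect * temp_std[:, None]
    planted_rows = []
    banned_seq_by_module: dict[int, set] = {m: set() for m in range(M)}
    for k, s_idx in enumerate(trans_sites):
        m = module_of_trans[k]
        site = sites[s_idx]
        factors[:, m] += config.eqtl_beta * centered[s_idx]
        banned_seq_by_module[m].add(layout.names.index(site.chrom))
        planted_rows.append(
            dict(site_id=site.id, chrom=site.chrom, pos=site.pos, target=f"M{m}",
                 target_type="module", module=f"M{m}", beta=config.eqtl_beta, label="trans")
        )

    # --- place genes; module members avoid their module's planted sequences
    gene_rows = []
    modules_map = {}
    for m in range(M):
        allowed = np.array([i for i in range(n_seq) if i not in banned_seq_by_module[m]])
        for j in range(gpm):
            si, start, end = _place_gene(rng, layout, allowed)
            gid = f"g{m:02d}_{j:03d}"
            gene_rows.append(
                dict(gene_id=gid, chrom=layout.names[si], start=start, end=end,
                     strand="+" if rng.random() < 0.5 else "-", is_tf=False)
            )
            modules_map[gid] = f"M{m}"
    genes = pd.DataFrame(gene_rows)
    n_tf = int(round(config.tf_fraction * len(genes)))
    if n_tf:
        tf_idx = rng.choice(len(genes), size=n_tf, replace=False)
        genes.loc[tf_idx, "is_tf"] = True

    # --- expression matrix
    expr = np.empty((n, M * gpm))
    col_ids = list(genes["gene_id"])
    col_module = np.array([int(modules_map[g][1:]) for g in col_ids])
    noise = rng.standard_normal((n, M * gpm)) * config.expr_noise_sd
    expr[:] = config.loading * factors[:, col_module] + noise

    # --- cis eQTL: relocate the target gene onto its SNP's sequence
    col_pos = {g: i for i, g in enumerate(col_ids)}
    for k, s_idx in enumerate(cis_sites):
        site = sites[s_idx]
        seq_i = site_seq[site.id]
        m = int(rng.integers(0, M))
        # the SNP's sequence must not carry one of the module's trans SNPs,
        # else the gene placement rule above would be violated
        tries = 0
        while seq_i in banned_seq_by_module[m] and tries < 10 * M:
            m = int(rng.integers(0, M))
            tries += 1
        if seq_i in banned_seq_by_module[m]:
            raise ValueError("cannot place cis eQTL: all modules ban its sequence")
        gid = f"g{m:02d}_{k:03d}"  # overwrite an existing member's location
        L = int(layout.lengths[seq_i])
        glen = int(rng.integers(1000, 20001))
        start = int(np.clip(site.pos - glen // 2, 1, max(L - glen, 1)))
        genes.loc[genes["gene_id"] == gid, ["chrom", "start", "end"]] = [
            layout.names[seq_i], start, min(start + glen - 1, L),
        ]
        expr[:, col_pos[gid]] += config.eqtl_beta * centered[s_idx]
        planted_rows.append(
            dict(site_id=site.id, chrom=site.chrom, pos=site.pos, target=gid,
                 target_type="gene", module=f"M{m}", beta=config.eqtl_beta, label="cis")
        )

    individuals = [f"Ind{i}" for i in range(n)]
    expr_df = pd.DataFrame(expr, index=individuals, columns=col_ids)
    factors_df = pd.DataFrame(
        factors, index=individuals, columns=[f"M{m}" for m in range(M)]
    )
    planted = pd.DataFrame(
        planted_rows,
        columns=["site_id", "chrom", "pos", "target", "target_type", "module", "beta", "label"],
    )
    eset = ExpressionSet(
        expr=expr_df,
        genes=genes,
        modules=pd.Series(modules_map, name="module"),
        tissue=config.tissue,
    )
    return eset, factors_df, planted, genes


# ---------------------------------------------------------------------------
# traits

def simulate_traits(
    config: SimConfig,
    factors: pd.DataFrame,
    covariates: pd.DataFrame,
    pheno_ids: list,
    rng: np.random.Generator,
):
    """Traits as weighted module factors plus covariate effects and noise.

    Trait t loads on module ``t mod M`` with weight
    ``trait_module_weight`` (standardized factor), plus temperature and
    order effects; only ``pheno_ids`` receive non-missing values.
    Returns ``(PhenotypeTable, trait_weights DataFrame)``.
    """
    individuals = list(factors.index)
    n = len(individuals)
    M = factors.shape[1]
    temp_std = (covariates["temperature"].to_numpy(dtype=float) - 20.0) / 8.0
    order_std = covariates["order"].to_numpy(dtype=float) - 0.5
    F = factors.to_numpy(dtype=float)
    F_std = (F - F.mean(axis=0)) / F.std(axis=0, ddof=1)
    data = covariates.copy()
    weights = []
    mask = np.isin(np.array(individuals), np.array(list(pheno_ids)))
    for t in range(config.n_traits):
        m = t % M
        y = (
            config.trait_module_weight * F_std[:, m]
            + config.trait_temp_effect * temp_std
            + config.trait_order_effect * order_std
            + rng.standard_normal(n) * config.trait_noise_sd
        )
        y = np.where(mask, y, np.nan)
        name = f"trait{t + 1}"
        data[name] = y
        weights.append(
            dict(trait=name, module=factors.columns[m], weight=config.trait_module_weight,
                 temp_effect=config.trait_temp_effect, order_effect=config.trait_order_effect,
                 noise_sd=config.trait_noise_sd)
        )
    traits = [w["trait"] for w in weights]
    table = PhenotypeTable(data=data[list(covariates.columns) + traits], traits=traits)
    return table, pd.DataFrame(weights)


# ---------------------------------------------------------------------------
# full dataset

def simulate_dataset(config: SimConfig | None = None, seed: int | None = None) -> SimulatedData:
    """Generate one complete study: genotypes, GLs, expression, traits, truth.

    ``seed`` overrides ``config.seed``.  A single Generator stream drives
    every draw, so the result is fully deterministic given the seed.
    """
    config = config or SimConfig()
    if seed is not None:
        config = replace(config, seed=int(seed))
    rng = np.random.default_rng(config.seed)
    genotypes, sites, maf = simulate_genotypes(config, rng)
    individuals = [f"Ind{i}" for i in range(config.n_individuals)]

    # covariates: half at each acclimation temperature, random order
    n = config.n_individuals
    temp = np.full(n, 12.0)
    temp[rng.permutation(n)[: n // 2]] = 28.0
    order = rng.integers(0, 2, size=n).astype(float)
    covariates = pd.DataFrame(
        {"temperature": temp, "order": order}, index=individuals
    )

    site_gls = simulate_gls(genotypes, sites, config.mean_depth, config.base_error, rng)
    eset_full, factors, planted, genes = simulate_expression(
        config, genotypes, sites, maf, rng, temperature=temp
    )

    # expression-profiled subset; trait-phenotyped subset nested within it
    subset = rng.permutation(n)[: max(config.n_expr, config.n_pheno)]
    expr_ids = sorted(individuals[i] for i in subset[: config.n_expr])
    pheno_ids = sorted(individuals[i] for i in subset[: config.n_pheno])
    eset = ExpressionSet(
        expr=eset_full.expr.loc[expr_ids],
        genes=eset_full.genes,
        modules=eset_full.modules,
        tissue=config.tissue,
    )

    phenotypes, trait_weights = simulate_traits(config, factors, covariates, pheno_ids, rng)
    truth = TruthSet(
        genotypes=genotypes, maf=maf, planted=planted, factors=factors,
        trait_weights=trait_weights,
    )
    truth.validate(sites, genes)
    return SimulatedData(
        config=config, layout=config.layout, sites=sites, site_gls=site_gls,
        individuals=individuals, expression=eset, phenotypes=phenotypes, truth=truth,
    )


def write_dataset(data: SimulatedData, outdir) -> dict:
    """Write a simulated study to disk in the pipeline's input formats.

    Emits sites.beagle, genes.gff3, modules.tsv, tf.tsv, expression.tsv,
    phenotypes.tsv, layout.tsv and truth.tsv; returns the path map.
    Re-reading these files with :mod:`lceqtl.io` reproduces the in-memory
    objects.
    """
    from pathlib import Path

    from .io import write_beagle_gl, write_gff_genes, write_phenotype_table

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "beagle": out / "sites.beagle",
        "gff": out / "genes.gff3",
        "modules": out / "modules.tsv",
        "tf": out / "tf.tsv",
        "expression": out / "expression.tsv",
        "phenotypes": out / "phenotypes.tsv",
        "layout": out / "layout.tsv",
        "truth": out / "truth.tsv",
    }
    write_beagle_gl(paths["beagle"], data.site_gls, individuals=data.individuals)
    write_gff_genes(paths["gff"], data.expression.genes)
    data.expression.modules.rename_axis("mrna").reset_index().to_csv(
        paths["modules"], sep="\t", index=False
    )
    data.expression.genes.loc[data.expression.genes["is_tf"], "gene_id"].to_csv(
        paths["tf"], sep="\t", index=False, header=["gene_id"]
    )
    data.expression.expr.to_csv(paths["expression"], sep="\t", index_label="individual")
    write_phenotype_table(paths["phenotypes"], data.phenotypes)
    data.layout.write(paths["layout"])
    data.truth.planted.to_csv(paths["truth"], sep="\t", index=False)
    return paths
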