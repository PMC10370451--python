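"""Readers, writers, site filtering and configuration.

All coordinates are 1-based inclusive internally (the VCF/GFF convention);
conversion to BED's 0-based half-open intervals happens only at export.
Supported formats: beagle genotype-likelihood text, sites-only VCF (import),
GFF3/GTF gene annotation, BED (export), and plain TSV tables for
phenotypes, expression, module assignments and transcription-factor lists.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genolik import SiteGL, SiteRecord, allele_freq_em_batch, stack_logliks

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "StructureError",
    "PipelineConfig",
    "PhenotypeTable",
    "GenomeLayout",
    "read_beagle_gl",
    "write_beagle_gl",
    "filter_sites",
    "FilterResult",
    "read_gff_genes",
    "write_gff_genes",
    "read_sites_vcf",
    "read_phenotype_table",
    "write_phenotype_table",
    "read_module_table",
    "read_tf_list",
    "sites_to_bed",
    "load_config",
]


class ParseError(ValueError):
    """A malformed record in an input file; the message names the line."""


class StructureError(ValueError):
    """Structurally inconsistent input (e.g. individual counts differ)."""


# ---------------------------------------------------------------------------
# configuration

@dataclass
class PipelineConfig:
    """Every tunable threshold of the pipeline, with its default.

    Values mirror the upstream filtering/association conventions for
    low-coverage data: sites are kept at minor allele frequency > 5% and
    site missingness < 10%, association tests require an expected minor
    allele count >= 10 and >= 10 high-credibility individuals (posterior
    >= 0.9) in each of the two most populous genotype classes,
    significance is Benjamini-Hochberg FDR < 0.05, linked hits within
    500 bp are pruned, and regulatory proximity means <= 5 kb.
    """

    maf_min: float = 0.05
    site_missing_max: float = 0.10
    ind_missing_max: float = 0.05
    min_count: int = 10
    min_high: int = 10
    posterior_high: float = 0.9
    fdr_alpha: float = 0.05
    prune_window: int = 500
    proximity_window: int = 5000
    top_k: int = 10
    ld_max_dist: int = 1000
    ld_bin_width: int = 100
    sensitivity_floor: float = 1.1102e-16
    min_complete_cases: int = 8

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        bad = set(raw) - known
        if bad:
            raise StructureError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)


def load_config(path=None) -> PipelineConfig:
    """Load a YAML config, or return defaults when ``path`` is None."""
    return PipelineConfig() if path is None else PipelineConfig.from_yaml(path)


# ---------------------------------------------------------------------------
# genome layout

@dataclass
class GenomeLayout:
    """Ordered reference sequences: large chromosomes plus small scaffolds.

    ``classes`` entries are ``"chromosome"`` or ``"scaffold"``.  The split
    matters downstream: cis/trans classification is sequence-level, and
    the chromosome-aware trans null weights sequences by their tested
    sites.
    """

    names: list
    lengths: list
    classes: list

    def __post_init__(self) -> None:
        if not self.names:
            raise ValueError("layout needs at least one sequence")
        if len(set(self.names)) != len(self.names):
            raise ValueError("sequence names must be unique")
        if len(self.names) != len(self.lengths) or len(self.names) != len(self.classes):
            raise ValueError("names/lengths/classes must align")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("sequence lengths must be positive")

    @property
    def total_length(self) -> int:
        return int(sum(self.lengths))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"name": self.names, "length": self.lengths, "class": self.classes})

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "GenomeLayout":
        df = pd.read_csv(path, sep="\t")
        return cls(list(df["name"]), [int(x) for x in df["length"]], list(df["class"]))


# ---------------------------------------------------------------------------
# beagle genotype-likelihood text format

def _marker_to_site(marker: str, a1: str, a2: str, lineno: int) -> SiteRecord:
    chrom, _, pos = marker.rpartition("_")
    if not chrom:
        raise ParseError(f"line {lineno}: marker {marker!r} is not of the form chrom_pos")
    try:
        ipos = int(pos)
    except ValueError as exc:
        raise ParseError(f"line {lineno}: marker {marker!r} has non-integer position") from exc
    codes = {"0": "A", "1": "C", "2": "G", "3": "T"}
    ref = codes.get(a1, a1.upper())
    alt = codes.get(a2, a2.upper())
    try:
        return SiteRecord(chrom=chrom, pos=ipos, ref=ref, alt=alt)
    except ValueError as exc:
        raise ParseError(f"line {lineno}: {exc}") from exc


def read_beagle_gl(path) -> list[SiteGL]:
    """Read a beagle genotype-likelihood text file.

    Expects the usual layout: a header row, then one row per marker with
    ``marker allele1 allele2`` followed by three likelihood columns per
    individual (genotypes 0/1/2 alternate copies).  Likelihoods are
    converted to max-normalized log-likelihoods.  Raises
    :class:`ParseError` for malformed rows (naming the line) and
    :class:`StructureError` when the column count is inconsistent.
    """
    sites: list[SiteGL] = []
    n_ind = None
    with open(path) as fh:
        header = fh.readline()
        if not header:
            raise StructureError(f"{path}: empty file")
        ncol = len(header.split())
        if ncol < 6 or (ncol - 3) % 3:
            raise StructureError(
                f"{path}: header has {ncol} columns; expected 3 + 3 per individual"
            )
        n_ind = (ncol - 3) // 3
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != ncol:
                raise StructureError(
                    f"line {lineno}: {len(parts) - 3} likelihood columns for "
                    f"{n_ind} individuals (expected {ncol - 3})"
                )
            site = _marker_to_site(parts[0], parts[1], parts[2], lineno)
            try:
                vals = np.array([float(x) for x in parts[3:]], dtype=float)
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-numeric likelihood value") from exc
            if np.any(vals < 0) or not np.all(np.isfinite(vals)):
                raise ParseError(f"line {lineno}: likelihoods must be finite and >= 0")
            lik = vals.reshape(n_ind, 3)
            if np.any(lik.max(axis=1) <= 0):
                raise ParseError(f"line {lineno}: an individual has all-zero likelihoods")
            with np.errstate(divide="ignore"):
                ll = np.log(lik)
            sites.append(SiteGL(site=site, loglik=ll))
    return sites


def write_beagle_gl(path, site_gls: list[SiteGL], individuals=None) -> None:
    """Write sites to beagle GL text, likelihoods sum-normalized per individual.

    ``individuals`` supplies header names; defaults to Ind0..IndN-1 (each
    repeated three times, as beagle expects).
    """
    if not site_gls:
        raise StructureError("no sites to write")
    n = site_gls[0].n_individuals
    if individuals is None:
        individuals = [f"Ind{i}" for i in range(n)]
    base_code = {"A": "0", "C": "1", "G": "2", "T": "3"}
    with open(path, "w") as fh:
        cols = ["marker", "allele1", "allele2"] + [i for ind in individuals for i in (ind,) * 3]
        fh.write("\t".join(cols) + "\n")
        for gl in site_gls:
            if gl.n_individuals != n:
                raise StructureError("inconsistent individual counts across sites")
            lik = gl.likelihoods()
            lik = lik / lik.sum(axis=1, keepdims=True)
            row = [
                gl.site.id,
                base_code.get(gl.site.ref, gl.site.ref),
                base_code.get(gl.site.alt, gl.site.alt),
            ] + [f"{v:.6g}" for v in lik.ravel()]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# site filtering

@dataclass
class FilterResult:
    """Outcome of site-level filtering.

    ``site_mask`` marks retained sites; ``flagged_individuals`` lists
    indices whose missingness exceeds the per-individual bound (they are
    flagged, never silently dropped — association sample sizes are small
    enough that dropping is a deliberate CLI decision).
    """

    retained: list
    site_mask: np.ndarray
    maf: np.ndarray
    site_missingness: np.ndarray
    individual_missingness: np.ndarray
    flagged_individuals: list


def filter_sites(
    site_gls: list[SiteGL],
    maf: np.ndarray | None = None,
    maf_min: float = 0.05,
    site_missing_max: float = 0.10,
    ind_missing_max: float = 0.05,
) -> FilterResult:
    """Retain biallelic sites with MAF > ``maf_min`` and site missingness
    < ``site_missing_max``; flag high-missingness individuals.

    ``maf`` may carry precomputed per-site allele frequencies (alt
    frequency or MAF; folding is applied); otherwise frequencies are
    estimated by the HWE EM.  Biallelic structure is enforced by the
    :class:`SiteRecord` container itself.  Idempotent: filtering a
    filtered set retains everything.
    """
    if not site_gls:
        return FilterResult([], np.zeros(0, bool), np.zeros(0), np.zeros(0), np.zeros(0), [])
    ll = stack_logliks(site_gls)
    miss = np.ptp(ll, axis=2) == 0
    site_missing = miss.mean(axis=1)
    ind_missing = miss.mean(axis=0)
    if maf is None:
        p, _, _ = allele_freq_em_batch(ll)
    else:
        p = np.asarray(maf, dtype=float)
    folded = np.minimum(p, 1.0 - p)
    mask = (folded > maf_min) & (site_missing < site_missing_max) & ~np.isnan(folded)
    flagged = [int(i) for i in np.nonzero(ind_missing > ind_missing_max)[0]]
    if flagged:
        logger.warning(
            "%d individual(s) exceed %.0f%% missingness: %s",
            len(flagged), 100 * ind_missing_max, flagged,
        )
    retained = [g for g, keep in zip(site_gls, mask) if keep]
    return FilterResult(retained, mask, folded, site_missing, ind_missing, flagged)


# ---------------------------------------------------------------------------
# annotation

def read_gff_genes(path, tf_ids=None, featuretype: str = "gene") -> pd.DataFrame:
    """Load gene intervals from GFF3/GTF.

    Returns a DataFrame with columns ``gene_id, chrom, start, end, strand,
    is_tf`` (1-based inclusive coordinates), sorted by (chrom, start).
    ``tf_ids`` is an iterable of gene ids to flag as transcription
    factors; with no list every ``is_tf`` is False.  Strand is parsed but
    carries no semantics downstream (distances are strand-symmetric).
    """
    import gffutils

    tf_set = set(tf_ids) if tf_ids is not None else set()
    try:
        db = gffutils.create_db(
            str(path), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises assorted types on bad input
        raise ParseError(f"{path}: cannot parse annotation ({exc})") from exc
    rows = []
    for feat in db.features_of_type(featuretype):
        if feat.end < feat.start:
            raise ParseError(f"{path}: gene {feat.id} has end < start")
        gid = feat.attributes.get("ID", [feat.id])[0] if feat.attributes else feat.id
        rows.append(
            dict(gene_id=gid, chrom=feat.seqid, start=int(feat.start),
                 end=int(feat.end), strand=feat.strand or ".", is_tf=gid in tf_set)
        )
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand", "is_tf"])
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def write_gff_genes(path, genes: pd.DataFrame, source: str = "lceqtl") -> None:
    """Write a gene table (as from :func:`read_gff_genes`) to GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{source}\tgene\t{row.start}\t{row.end}\t.\t"
                f"{getattr(row, 'strand', '.')}\t.\tID={row.gene_id}\n"
            )


def read_sites_vcf(path) -> list[SiteRecord]:
    """Import biallelic SNP sites from a (sites-only) VCF.

    Multiallelic or non-SNP records are skipped with a warning — the
    pipeline's site container is strictly biallelic.
    """
    from cyvcf2 import VCF

    sites = []
    skipped = 0
    for var in VCF(str(path)):
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            skipped += 1
            continue
        sites.append(SiteRecord(chrom=var.CHROM, pos=var.POS, ref=var.REF, alt=var.ALT[0]))
    if skipped:
        warnings.warn(f"{path}: skipped {skipped} non-biallelic/non-SNP record(s)")
    return sites


def sites_to_bed(df: pd.DataFrame) -> pd.DataFrame:
    """Convert a table with ``chrom, pos`` (1-based) to BED (0-based half-open)."""
    out = pd.DataFrame(
        {"chrom": df["chrom"], "start": df["pos"].astype(int) - 1, "end": df["pos"].astype(int)}
    )
    for col in ("site_id", "phenotype", "classification"):
        if col in df.columns:
            out[col] = df[col].values
    return out


# ---------------------------------------------------------------------------
# tabular inputs

@dataclass
class PhenotypeTable:
    """Trait values and covariates per individual.

    ``data`` is indexed by individual id and holds real-valued trait
    columns (missing allowed) plus the covariates: acclimation
    ``temperature`` (12 or 28 degrees C) and acclimation ``order``
    (categorical, coded 0/1 for 12-then-28 vs 28-then-12).
    """

    data: pd.DataFrame
    traits: list
    covariates: tuple = ("temperature", "order")

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise StructureError("duplicate individual ids in phenotype table")
        for t in self.traits:
            if t not in self.data.columns:
                raise StructureError(f"trait column {t!r} missing")
            if self.data[t].notna().sum() < 1:
                raise StructureError(f"trait {t!r} has no non-missing values")
        for c in self.covariates:
            if c not in self.data.columns:
                raise StructureError(f"covariate column {c!r} missing")
        phenotyped = self.data[self.traits].notna().any(axis=1)
        for c in self.covariates:
            if self.data.loc[phenotyped, c].isna().any():
                raise StructureError(f"covariate {c!r} missing for phenotyped individuals")

    @property
    def individuals(self) -> list:
        return list(self.data.index)

    def covariate_matrix(self, which=("temperature", "order")) -> pd.DataFrame:
        """Numeric covariate columns (temperature centered at 20 C)."""
        out = {}
        for c in which:
            col = self.data[c]
            out[c] = pd.to_numeric(col, errors="coerce")
        return pd.DataFrame(out, index=self.data.index)


def read_phenotype_table(path, covariates=("temperature", "order")) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    traits = [c for c in df.columns if c not in covariates]
    return PhenotypeTable(data=df, traits=traits, covariates=tuple(covariates))


def write_phenotype_table(path, table: PhenotypeTable) -> None:
    table.data.to_csv(path, sep="\t", index_label="individual")


def read_module_table(path) -> pd.Series:
    """mRNA -> module assignment TSV (columns ``mrna, module``)."""
    df = pd.read_csv(path, sep="\t")
    if not {"mrna", "module"} <= set(df.columns):
        raise StructureError(f"{path}: expected columns 'mrna' and 'module'")
    if df["mrna"].duplicated().any():
        raise StructureError(f"{path}: an mRNA is assigned to more than one module")
    return df.set_index("mrna")["module"]


def read_tf_list(path) -> set:
    """Transcription-factor gene ids, one per line (first TSV column)."""
    ids = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.add(line.split("\t")[0])
    ids.discard("gene_id")  # tolerate a header
    return ids
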