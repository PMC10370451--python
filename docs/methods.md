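# Methods

## Setting

The package targets a study design common in ecological genomics: a few
hundred wild-caught individuals sequenced at low coverage (~4×), a subset
of them (~25 per test) phenotyped for physiological traits and profiled
for tissue-specific mRNA expression, and expression pre-summarized into
co-expression modules by an upstream network analysis. The questions the
pipeline answers are (i) which SNPs associate with traits, single mRNAs,
and module eigengenes; (ii) whether the resulting eQTL act in cis or in
trans; and (iii) what the catalog's architecture looks like — hotspots,
sharing across modules, site heterozygosity.

## Genotype-likelihood model

All computations start from per-individual genotype likelihoods
`L_i(g)`, g ∈ {0, 1, 2} alternate-allele copies, stored max-normalized in
log space. An individual with no reads has a flat row, detected
structurally; flat rows contribute the prior only and are excluded from
effective sample sizes.

**Allele frequency.** The ML frequency under Hardy–Weinberg maximizes
`Σ_i log Σ_g L_i(g)·HWE(g; p)` by EM: each iteration replaces p with the
posterior mean dosage over informative individuals divided by two.
The likelihood in p is unimodal, so the fixed start p₀ = 0.25 affects
only iteration count; convergence is |Δp| < 1e−6 or 200 iterations. With
certain genotypes the update lands on the allele-count frequency in a
single step, so the estimator reduces exactly to counting in the
certainty limit. Expected heterozygosity is He = 2p(1−p), computed from
the EM frequency by default (a hard-call variant is exposed as
`lceqtl report --hard-call`, since either convention appears in
practice).

**Posteriors and dosages.** Genotype posteriors combine the likelihoods
with the HWE prior at the estimated frequency; the expected dosage
`d = P(1) + 2P(2)` is the score-test regressor. If the prior is
degenerate (p ∈ {0,1}) and excludes all likelihood support, the prior is
returned — such sites are monomorphic and fail association filters
anyway.

## Association

The score test fits the null `y ~ X` (intercept plus covariates) by least
squares and scores the addition of the dosage:
`T = (d̃ᵀr)² / (σ̂²·d̃ᵀd̃)` with `σ̂² = RSS/n` (the ML variance, as usual
for score tests) and d̃ the dosage residualized on X; p is the upper
χ²₁ tail. With certain genotypes this is algebraically the classical
score statistic for adding d to the regression (verified against a
least-squares oracle to 1e−8). With uncertain genotypes the
expected-dosage form is an approximation to the full latent-genotype
score; rather than assuming its adequacy at ~4×, the test suite measures
the empirical type-I error at the study's conditions (n = 50, depth 4×,
MAF 0.2, an active temperature covariate) and requires it to sit in
[0.035, 0.065] at α = 0.05 with uniform p-values.

Covariates follow the design under which the phenotypes were measured:
acclimation temperature for every phenotype, plus acclimation order for
whole-animal and cardiac traits. The simulator deliberately routes
temperature into both expression and traits so that omitting the
covariate visibly inflates the null — a property the suite asserts.

**Site filters.** Two pre-test filters mirror standard genotype-
likelihood association practice: the expected minor-allele count must
reach 10 (`minCount`), and each of the two most populous genotype classes
must contain at least 10 individuals whose maximum genotype posterior is
≥ 0.9 (`minHigh`). Published descriptions of the minHigh rule vary
between tool versions, so the implementation reports both flags
separately and the thresholds (10, 10, 0.9) are config keys. When a site
fails both, the scalar status reports the allele-count failure, which is
the more fundamental of the two.

**Multiplicity and linkage.** Benjamini–Hochberg adjustment (delegated to
statsmodels) is applied within one phenotype's family of tested sites —
never pooled across phenotypes. Significance is adjusted p < 0.05.
Within a phenotype, significant hits are pruned greedily by ascending raw
p: a hit is kept only if no stronger kept hit lies within 500 bp on the
same sequence (ties broken by position, making the output invariant to
input order). The 500-bp window reflects the fast LD decay typical of
large outbred marine populations, and is itself checkable with the
package's decay module. An optional sensitivity filter restricts
summaries to hits with raw p above 1.1102e−16, the floor below which
χ² tail probabilities lose numerical meaning.

## Expression summaries

Module assignments are inputs; the package computes only what the
association stage consumes. The module eigengene is the first principal
component of the module's standardized expression (columns mean-imputed
then z-scored; zero-variance mRNAs dropped with a warning), rescaled to
unit variance with the sign set so the mean member correlation is
non-negative — fully deterministic and invariant to gene order. Module
membership (kME) is the Pearson correlation of each member with the ME,
and the top k = 10 members by kME (ties by gene id) become the
single-mRNA phenotypes. Ranking uses signed kME; an absolute-value
ranking can be selected where anti-correlated module halves matter.

## LD

Pairwise r² comes from a four-parameter haplotype-frequency EM on the
unphased two-locus likelihood, starting at linkage equilibrium
(products of the single-site ML frequencies), tolerance 1e−6, at most
500 iterations. The EM enumerates the 16 ordered haplotype pairs; the
E-step distributes each individual's likelihood mass over compatible
pairs and the M-step renormalizes expected haplotype counts. r² is
invariant to allele relabelling, undefined for monomorphic sites (a
dedicated error), and equals the classic hard-call haplotype EM at
infinite depth. When phase is identifiable from genotypes (no double
heterozygotes), the EM reproduces direct haplotype-count r² to 1e−6 —
with double heterozygotes the unphased MLE is the correct target and
need not equal phased counting. Decay tables bin same-sequence pairs by
distance; cross-sequence pairs are excluded (distance undefined) and
empty bins are reported empty rather than zero.

## Architecture analyses

**Cis/trans.** Classification is sequence-level: an eQTL is trans iff its
SNP is on a different chromosome/scaffold than the target gene,
regardless of distance (a distance-based override `--cis-max-dist` style
rule was considered and rejected as the default because the sequence
rule is the convention the catalog summaries assume; distance to the
nearest gene boundary — not the TSS, which annotation does not reliably
give — is reported for cis hits). Eigengene eQTL are never classified:
a module has no single location. Instead each is checked for membership
proximity: is the SNP within 5 kb of *any* gene of the associated
module?

**Chromosome-aware trans null.** Under random placement, an eQTL whose
target sits on sequence s is trans with probability
`1 − (tested sites on s)/(total tested sites)`. Expected cis/trans
counts are sums of these probabilities over the catalog and are compared
with observed counts by a 1-df goodness-of-fit χ². The statistic is
slightly conservative when per-eQTL probabilities vary (the cis count is
a sum of non-identical Bernoullis); with uniform site geography its
rejection rate is nominal, which the acceptance suite verifies with
2,000 random-placement replicates. Results flag expected cells < 5,
where the χ² approximation is unreliable.

**Hotspots** are SNPs associated with ≥ 2 distinct mRNAs within one
tissue; per-SNP and per-mRNA association counts (mean ± sd, max) are
reported per tissue because catalogs are tissue-specific.

**Proximity.** A SNP is genic if inside any gene interval (all overlaps
reported — nested genes are not resolved), and TF-proximal if a
transcription-factor gene lies within an inclusive 5,000 bp. Distances
are strand-symmetric.

**Sharing.** The sharing unit is the unordered pair of *tested* mRNAs;
the indicator is whether their eQTL site sets intersect (identical SNP —
a gene-level variant is available through the overlap utilities).
Within-module pairs are compared with among-module pairs by a Welch
t-test; all-share and no-share configurations are reported as
degenerate no-difference outcomes rather than errors.

**Heterozygosity.** Focal vs background He sets are compared by Welch
t-test, with an optional permutation test (focal-sized resamples from the
background, default 10,000) that remains valid for very small focal sets.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
with defaults at the emulated study's stated conditions:

| parameter | default | reason |
|---|---|---|
| individuals genotyped | 172 | study cohort size |
| phenotyped/profiled subset | 25 | typical per-test sample size (22–35) |
| mean depth | 4.1× Poisson | study coverage |
| base error ε | 0.01 | typical Illumina post-filter rate |
| MAF | Uniform(0.05, 0.5) | sites below 5% MAF are pre-filtered |
| genome | 24 × 30 Mb chromosomes + 50 scaffolds (21.6% of length) | assembly geometry |
| sites | 5,000 | desk-scale stand-in for ~1.4 M |
| modules | 10 × 30 genes, loading λ = 0.8 | desk-scale module structure with realistic kME (~0.8) |
| planted eQTL | 20 trans (factor-level) + 2 cis, β = 1 | large-effect regulators, the detectable regime at these n |
| expression noise sd | 0.6 | keeps member-gene kME near λ |
| trait model | weight 1 on one module factor; temperature 0.5, order 0.25, noise 0.5 | traits substantially but not fully explained by modules |

Genotypes are Binomial(2, p) at HWE; read counts Poisson; alternate-read
counts Binomial(m, g/2·(1−ε) + (1−g/2)·ε), with likelihoods from the
same binomial model. Trans eQTL act on module latent factors — one SNP
perturbs a factor that all member genes load on — so hotspots arise
mechanistically rather than by independently planting per-gene effects,
which is what gives the hotspot detector a well-defined target. Member
genes are placed on sequences other than their module's planted SNPs and
cis targets share their SNP's sequence, making cis/trans labels
generative truth. A single seeded `numpy.random.Generator` drives every
draw, so datasets are bit-reproducible across platforms, and all emitted
files re-read to the in-memory objects.

What the generator does *not* emulate: population structure and
admixture (the emulated design found none), linkage between nearby sites
(sites are independent, so LD-decay realism comes from dedicated block
fixtures, not the main generator), read-level artifacts (mapping bias,
duplicates), count-distributed expression (expression is Gaussian
around the factor model), and residual correlation between tissues
(tissues are independent replicate expression sets). Passing tests
therefore demonstrate statistical correctness of the estimators and the
end-to-end plumbing under the assumed model — not robustness to
structure, batch effects, or model misspecification in real data.

### Detection limits worth knowing

* A planted cis eQTL adds genotype variance to its target gene, which
  *lowers* that gene's kME; with 30 genes per module the cis target
  often falls outside the tested top ten, so cis effects are
  recoverable only when their target ranks high. This mirrors a real
  property of the top-k design, not a simulator artifact.
* At the MAF floor (0.05) a factor-level eQTL explains only ~5% of
  factor variance; at n = 300 such sites sit at the edge of genome-wide
  BH significance, so recovery rates hover near (usually above) 90%.

## Numerical choices

* EM tolerances: 1e−6 on frequencies (both EMs), iteration caps 200
  (single-site) and 500 (two-locus); likelihood traces are exposed and
  asserted non-decreasing in tests.
* Score test guards: dosage declared collinear when its residual squared
  norm falls below 1e−12 of its squared norm; p-values floored at the
  smallest positive double to keep BH input valid.
* Eigengene sign: flipped when mean member correlation is negative;
  ties in top-k broken by gene id; ME variance uses ddof = 1.
* Pruning ties: (raw p, chromosome, position) lexicographic.
* Degenerate inputs raise typed errors (all-missing site, monomorphic
  LD pair, empty He set) or return flagged results (undefined trans
  test, degenerate sharing test) rather than NaN-propagating silently.

## Problem sizes used in validation

The test suite exercises the score-test calibration at 2,000 null
replicates, FDR control at 500 × 1,000 p-values, trans-null calibration
at 2,000 random placements of 1,000 eQTL, pruning against an independent
greedy oracle over ~900 enumerated configurations, eigengene recovery
over 100 replicates, and one full end-to-end recovery run (300
individuals, 5,000 sites, 10 modules, 22 planted eQTL at 30× depth) —
sizes chosen so the entire suite completes in about a minute on one CPU
while keeping every Monte-Carlo band tight enough to be meaningful.
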