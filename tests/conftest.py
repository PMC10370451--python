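"""Shared fixtures: certain-genotype GL builders and a small simulated study."""

import numpy as np
import pytest
from hypothesis import settings

from lceqtl.genolik import SiteGL, SiteRecord
from lceqtl.simulate import SimConfig, simulate_dataset

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_certain_gl(genotypes, chrom="chr1", pos=100, ref="A", alt="C") -> SiteGL:
    """A SiteGL whose likelihoods are certain at the given genotypes.

    Genotype -1 encodes a missing individual (flat likelihoods).
    """
    g = np.asarray(genotypes, dtype=int)
    ll = np.full((len(g), 3), -np.inf)
    ll[np.arange(len(g)), np.clip(g, 0, 2)] = 0.0
    ll[g < 0] = 0.0
    return SiteGL(site=SiteRecord(chrom=chrom, pos=pos, ref=ref, alt=alt), loglik=ll)


@pytest.fixture(scope="session")
def certain_gl_factory():
    return make_certain_gl


@pytest.fixture(scope="session")
def small_dataset():
    """A quick end-to-end study: 60 individuals, 300 sites, 3 modules."""
    cfg = SimConfig(
        n_individuals=60, n_pheno=40, n_expr=40, n_sites=300,
        n_modules=3, genes_per_module=12, n_trans_eqtl=3, n_cis_eqtl=1,
        mean_depth=8, seed=7,
    )
    return simulate_dataset(cfg)
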