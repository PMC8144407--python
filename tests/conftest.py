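import numpy as np
import pytest
import scipy.sparse as sp

import hidgenome as hg
from hidgenome.catalog import MutationCatalog, VariantKey


def make_catalog(incidence, labels=None, chrom="1", start_pos=1000):
    """Build a catalog from a dense 0/1 array; variant j at start_pos + j."""
    X = np.asarray(incidence, dtype=np.int8)
    n, d = X.shape
    variants = [
        VariantKey(chrom, start_pos + j, "C", "T", "A", "A") for j in range(d)
    ]
    return MutationCatalog(
        samples=[f"s{i}" for i in range(n)],
        variants=variants,
        incidence=sp.csr_matrix(X),
        labels=list(labels) if labels is not None else None,
    )


@pytest.fixture(scope="session")
def tiny_config():
    return hg.SimulationConfig(
        n_per_site=25,
        chrom_lengths={"1": 60_000_000, "2": 60_000_000},
        n_genes=10,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    catalog, tables, truth = hg.simulate_cohort(tiny_config, seed=7)
    return catalog, tables, truth


@pytest.fixture(scope="session")
def tiny_fit(tiny_config, tiny_cohort):
    """A full small pipeline: meta-design, screen, design, CV-tuned fit."""
    catalog, tables, truth = tiny_cohort
    meta = hg.assemble_meta_design(
        catalog, chrom_lengths=tiny_config.chrom_lengths,
        gene_intervals=tables["genes"],
    )
    screen = hg.screen_catalog(catalog, d0=40)
    design = hg.assemble_design(catalog, meta, screen)
    model = hg.fit(design, catalog.labels, n_lambda=10, lambda_min_ratio=1e-2,
                   cv_folds=3, seed=0, tol=1e-7, max_iter=1500)
    return catalog, meta, screen, design, model
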