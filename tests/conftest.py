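import numpy as np
import pandas as pd
import pytest

from somaqtl import SimConfig, simulate_cohort
from somaqtl.simulate import simulate_genotypes, simulate_sample_meta


@pytest.fixture(scope="session")
def small_cohort():
    """A compact default-scenario cohort shared across read-only tests."""
    return simulate_cohort(n_samples=300, n_variants=100, n_analytes=40, seed=7)


@pytest.fixture(scope="session")
def small_config(small_cohort):
    return small_cohort.config


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_genotypes(n_samples=200, n_variants=50, seed=0, **kw):
    cfg = SimConfig(n_samples=n_samples, n_variants=n_variants,
                    n_analytes=5, seed=seed, **kw)
    return simulate_genotypes(cfg)


def make_meta(n_samples=200, seed=0, **kw):
    cfg = SimConfig(n_samples=n_samples, n_variants=10, ld_block_size=10,
                    n_analytes=5, seed=seed, **kw)
    return simulate_sample_meta(cfg)


@pytest.fixture()
def toy_protein_matrix():
    """20 samples x 6 analytes across two dilution groups, reproducible."""
    from somaqtl import ProteinMatrix
    rng = np.random.default_rng(5)
    sids = pd.Index([f"S{i}" for i in range(20)], name="sample_id")
    aids = pd.Index([f"A{j}" for j in range(6)], name="analyte_id")
    values = pd.DataFrame(rng.normal(10, 1, (20, 6)), index=sids, columns=aids)
    analytes = pd.DataFrame({
        "gene_symbol": [f"G{j}" for j in range(6)],
        "chrom": "1",
        "gene_start": np.arange(6) * 100_000 + 1_500_000,
        "gene_end": np.arange(6) * 100_000 + 1_520_000,
        "dilution": ["20%", "20%", "20%", "1%", "1%", "0.005%"],
    }, index=aids)
    return ProteinMatrix(values, analytes)
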