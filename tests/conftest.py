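import numpy as np
import pandas as pd
import pytest

import triomics as t


@pytest.fixture(scope="session")
def small_geno():
    """120 accessions x 200 SNPs on 2 chromosomes, fixed seed."""
    return t.simulate.generate_genotypes(
        n_accessions=120, n_snps=200, n_chromosomes=2, seed=11
    )


@pytest.fixture(scope="session")
def identity_K(small_geno):
    n = small_geno.n_accessions
    return pd.DataFrame(
        np.eye(n), index=small_geno.accessions, columns=small_geno.accessions
    )


@pytest.fixture(scope="session")
def small_panel(small_geno):
    truth = t.TruthTable()
    panels = t.simulate.generate_metabolome(
        small_geno, truth, n_metabolites=40, n_years=2, seed=12
    )
    return panels


@pytest.fixture(scope="session")
def small_expr(small_geno):
    truth = t.TruthTable()
    for j in range(30):
        truth.planted_modules[f"gene{j:05d}"] = 1 + j % 2
    return t.simulate.generate_expression(small_geno, truth, n_genes=80, seed=13)
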