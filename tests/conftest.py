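import numpy as np
import pandas as pd
import pytest

from adipoclock import synthdata
from adipoclock.types import OmicsMatrix


@pytest.fixture(scope="session")
def small_design():
    spec = synthdata.DesignSpec(donors_per_group=4, n_sham=4, seed=11)
    return synthdata.generate_design(spec)


@pytest.fixture(scope="session")
def small_clock():
    return synthdata.generate_linear_clock(
        30, density=0.8, coef_scale=0.5, intercept=10.0, seed=7
    )


@pytest.fixture(scope="session")
def noiseless_expression(small_design, small_clock):
    counts, truth = synthdata.simulate_expression(
        small_design,
        small_clock,
        group_shifts={"OY": -5.0, "YO": 4.0},
        dispersion=0.0,
        n_genes=200,
        seed=3,
    )
    return counts, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def counts_matrix(values, genes=None, samples=None) -> OmicsMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return OmicsMatrix(pd.DataFrame(values, index=genes, columns=samples), "counts")


def beta_matrix(values, cpgs=None, samples=None) -> OmicsMatrix:
    values = np.asarray(values, dtype=float)
    cpgs = cpgs or [f"cg{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return OmicsMatrix(pd.DataFrame(values, index=cpgs, columns=samples), "beta")
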