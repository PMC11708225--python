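"""Shared fixtures: small synthetic datasets generated at test time."""

import numpy as np
import pytest

from mageit.data_model import MarkerSet, TestInputs, WeightScheme
from mageit.kernels import build_kernels


def make_inputs(
    n=80,
    p=6,
    m=2,
    seed=0,
    trait_type="continuous",
    maf=None,
    binary_prevalence=0.4,
):
    """Random aligned (y, E, X, G) with a polymorphic marker set."""
    rng = np.random.default_rng(seed)
    if maf is None:
        maf = np.concatenate([rng.uniform(0.05, 0.4, p // 2), rng.uniform(0.02, 0.05, p - p // 2)])
    dosages = rng.binomial(2, maf, size=(n, p)).astype(float)
    # guard against monomorphic draws at small n
    for j in range(p):
        if len(np.unique(dosages[:, j])) == 1:
            dosages[0, j] = 1.0
    markers = MarkerSet.from_dosages(dosages)
    covariates = np.column_stack([rng.normal(50, 10, n), rng.binomial(1, 0.5, n)])[:, :m]
    env = rng.binomial(1, 0.5, n).astype(float)
    if trait_type == "binary":
        y = rng.binomial(1, binary_prevalence, n).astype(float)
    else:
        y = rng.normal(0, 1, n)
    return TestInputs(
        phenotype=y,
        environment=env,
        covariates=covariates,
        markers=markers,
        trait_type=trait_type,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def inputs():
    return make_inputs()


@pytest.fixture
def ran_bundle(inputs):
    return build_kernels(inputs, mode="random_main")


@pytest.fixture
def fix_bundle(inputs):
    return build_kernels(inputs, mode="fixed_main")


@pytest.fixture
def scheme():
    return WeightScheme()
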