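"""Shared fixtures: expensive synthetic datasets are built once per session."""

import numpy as np
import pytest

from copulamodules.parametric import ParametricCopula, sample_parametric
from copulamodules.synthetic import BenchmarkSpec, make_benchmark


@pytest.fixture(scope="session")
def clayton5():
    return ParametricCopula("clayton", 5.0)


@pytest.fixture(scope="session")
def frank6():
    return ParametricCopula("frank", 6.0)


@pytest.fixture(scope="session")
def clayton_sample_50k(clayton5):
    return sample_parametric(clayton5, 50_000, seed=101)


@pytest.fixture(scope="session")
def frank_sample_50k(frank6):
    return sample_parametric(frank6, 50_000, seed=102)


@pytest.fixture(scope="session")
def bench2():
    """2-copula validation matrix (Frank 6 + Clayton 5), full sample size."""
    return make_benchmark(BenchmarkSpec(case=2, samples_per_copula=20_000,
                                        seed=42))


@pytest.fixture(scope="session")
def bench6_scaled():
    """6-copula validation matrix at the scaled-down sample size."""
    return make_benchmark(BenchmarkSpec(case=6, samples_per_copula=5_000,
                                        seed=0))
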