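import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from panclock.datamodel import BetaMatrix, SampleSheet
from panclock.simulate import make_fixture

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny():
    return make_fixture("tiny")


@pytest.fixture(scope="session")
def two_species():
    return make_fixture("two-species")


@pytest.fixture(scope="session")
def three_tissue():
    return make_fixture("three-tissue")


@pytest.fixture()
def small_beta():
    values = pd.DataFrame(
        [[0.1, 0.4], [0.5, 0.6], [0.8, 0.9]],
        index=["cg1", "cg2", "cg3"],
        columns=["s1", "s2"],
    )
    return BetaMatrix(values)


@pytest.fixture()
def small_sheet():
    return SampleSheet(pd.DataFrame({
        "sample_id": ["s1", "s2"],
        "species": ["vervet", "vervet"],
        "tissue": ["blood", "blood"],
        "sex": ["F", "M"],
        "age": [1.0, 10.0],
    }))


def random_design(rng: np.random.Generator, n: int, p: int) -> tuple[pd.DataFrame, np.ndarray]:
    """Small regression instance with betas in (0,1) and a linear signal."""
    X = rng.uniform(0.05, 0.95, (n, p))
    coefs = rng.normal(0, 2, min(3, p))
    y = X[:, : len(coefs)] @ coefs + rng.normal(0, 0.5, n)
    cols = [f"cg{j:03d}" for j in range(p)]
    return pd.DataFrame(X, columns=cols), y
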