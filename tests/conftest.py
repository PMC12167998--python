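import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from geosfs import ModelParams, SamplingKernel

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference_regime() -> ModelParams:
    """The parameter regime used throughout the worked examples:
    sigma=10, s=0.01 (ell_c=100), mu=1e-9, rho=20, L=1000 (N=2e7)."""
    return ModelParams(sigma=10.0, s=0.01, mu=1e-9, rho=20.0, L=1000.0)


@pytest.fixture(scope="session")
def gaussian_w100() -> SamplingKernel:
    return SamplingKernel.gaussian(100.0)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but spatially structured cohort shared across tests."""
    from geosfs.cohort import CohortSpec, VariantClass, generate_cohort

    spec = CohortSpec(
        n_individuals=800,
        L=200.0,
        sigma=8.0,
        classes=(
            VariantClass("weak", 0.02, 1e-5, 150),
            VariantClass("strong", 0.1, 1e-5, 150),
        ),
        seed=7,
    )
    return spec, generate_cohort(spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
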