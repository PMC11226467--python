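import numpy as np
import pytest

from voxlogit.phantom import PhantomParams, generate_cohort


@pytest.fixture(scope="session")
def small_params() -> PhantomParams:
    """Desk-scale phantom geometry shared by the slower fixtures."""
    return PhantomParams(
        shape=(16, 16, 16),
        core_radius_mm=5.0,
        penumbra_radius_mm=10.0,
        coverage_margin_mm=6.0,
        center_jitter_mm=1.5,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_params):
    """90 phantom patients: enough coverage for 7-predictor GLM masks."""
    return generate_cohort(small_params, 90)


@pytest.fixture(scope="session")
def fitted_model(small_cohort):
    from voxlogit.glm import PredictorSet, fit_voxelwise

    pset = PredictorSet(
        ("intercept", "cbv", "cbf", "tmax", "recan", "recan:cbv", "recan:cbf"), fwhm=0.0
    )
    return fit_voxelwise(small_cohort, pset)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
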