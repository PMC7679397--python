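import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from idiorsa.pipeline import (  # noqa: E402
    build_personal_models,
    cohort_data_from_synthetic,
    prepare_patterns,
)
from idiorsa.synthetic import CohortConfig, generate_cohort  # noqa: E402


def small_cohort_config(**overrides) -> CohortConfig:
    """A compact cohort for fast tests: 8 participants, 120 voxels, 2 regions."""
    base = dict(
        n_participants=8,
        grid_shape=(6, 5, 4),
        n_rois=2,
        signal_rois=(1, 2),
        vocab_size=100,
        seed=3,
    )
    base.update(overrides)
    return CohortConfig(**base)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_cohort_config())


@pytest.fixture(scope="session")
def small_pipeline(small_cohort):
    """Models and patterns computed once for the small cohort."""
    data = cohort_data_from_synthetic(small_cohort)
    models = build_personal_models(data)
    patterns = prepare_patterns(data, voxel_k=50)
    return data, models, patterns


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
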