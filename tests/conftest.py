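import numpy as np
import pytest

from cortsig.staging import split_reference
from cortsig.surface import build_icosphere
from cortsig.synthetic import CohortConfig, EffectPatch, generate_cohort


@pytest.fixture(scope="session")
def ico2():
    return build_icosphere(2)


@pytest.fixture(scope="session")
def ico3():
    return build_icosphere(3)


@pytest.fixture(scope="session")
def ico4():
    return build_icosphere(4)


def tiny_config(**overrides) -> CohortConfig:
    """Order-3 cohort small enough for unit tests but with the default
    spatial-effect structure."""
    kwargs = dict(
        mesh_order=3,
        group_sizes={"CS-": 40, "CS+": 16, "IMP+": 12},
    )
    kwargs.update(overrides)
    return CohortConfig(**kwargs)


def null_config(n_ref=20, n_adv=15, mesh_order=3) -> CohortConfig:
    """No effect patches at all: group labels carry no thickness signal."""
    return CohortConfig(
        mesh_order=mesh_order,
        group_sizes={"CS-": n_ref, "CS+": 0, "IMP+": n_adv},
        patches=(),
        age_slope_mm_per_year=0.0,
        age_mean={"CS-": 45.0, "CS+": 45.0, "IMP+": 45.0},
        age_sd={"CS-": 6.0, "CS+": 6.0, "IMP+": 6.0},
    )


@pytest.fixture(scope="session")
def tiny_cohort():
    cohort = generate_cohort(tiny_config(), seed=123)
    split_reference(cohort, seed=124)
    return cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size default cohort (order-4 meshes, 106/45/27) with 80/20 split."""
    cohort = generate_cohort(CohortConfig(), seed=42)
    split_reference(cohort, seed=43)
    return cohort
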