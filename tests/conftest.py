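import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_unit_quats(rng, n):
    q = rng.standard_normal((n, 4))
    return q / np.linalg.norm(q, axis=1, keepdims=True)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Two participants, three trials each — fast shared fixture."""
    from imu_qc.synthetic import CohortConfig, generate_cohort

    return generate_cohort(
        CohortConfig(n_participants=2, trials_per_participant=3, seed=7)
    )


@pytest.fixture(scope="session")
def tiny_table(tiny_cohort):
    from imu_qc.report import build_segment_table

    return build_segment_table(tiny_cohort)


@pytest.fixture(scope="session")
def midsize_cohort():
    """Six participants at full trial count for statistics-level checks."""
    from imu_qc.synthetic import CohortConfig, generate_cohort

    return generate_cohort(CohortConfig(n_participants=6, seed=21))


@pytest.fixture(scope="session")
def midsize_table(midsize_cohort):
    from imu_qc.report import build_segment_table

    return build_segment_table(midsize_cohort)
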