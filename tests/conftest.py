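import numpy as np
import pytest

from tempovar.series import RoiTimeSeries
from tempovar.synthetic import CohortDesign, BehaviorCoupling, default_model, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_series(rng):
    """200-volume, 8-region white-noise series at TR = 2 s."""
    return RoiTimeSeries(
        rng.standard_normal((200, 8)),
        [f"r{i}" for i in range(8)],
        tr_seconds=2.0,
    )


@pytest.fixture(scope="session")
def small_model():
    return default_model(n_regions=6, mean_dwell=20.0)


@pytest.fixture(scope="session")
def small_cohort(small_model):
    """4 patients x 3 stages + 4 controls x 1 baseline, 120 volumes."""
    design = CohortDesign(
        n_per_group=4,
        n_volumes=120,
        coupling=BehaviorCoupling(slope=1.0, noise_sd=0.02),
        base_score=30.0,
        score_sd=6.0,
        recovery_gain=10.0,
        coupled_region="PreCG_L",
        seed=99,
    )
    cohort, truth = simulate_cohort(design, small_model)
    return design, cohort, truth
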