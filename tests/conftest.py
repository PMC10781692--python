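import numpy as np
import pytest

from tmsdcm.synthetic import (
    NCECM_REGIONS,
    CohortConfig,
    FluctuationSpec,
    generate_cohort,
    make_block_atlas,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def block_atlas():
    """Small labelled atlas shared across connectivity tests."""
    labels, affine, label_map = make_block_atlas(NCECM_REGIONS, (14, 14, 12))
    return labels, affine, label_map


@pytest.fixture(scope="session")
def small_cohort():
    """Scores-only cohort (no time series): cheap, deterministic."""
    cfg = CohortConfig(n_subjects=26, n_motion_outliers=0, n_missing_week4=1,
                       timeseries=False, seed=7)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def white_fluct():
    return FluctuationSpec(alpha_state=0.01, beta_state=0.0, alpha_obs=0.0, beta_obs=0.0)
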