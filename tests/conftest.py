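import dataclasses

import numpy as np
import pytest

from wmhtremor.synthetic import SyntheticCohortConfig, generate_atlas, generate_tissue_volume


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale rendered cohort: small grid, lesion burden scaled to fit."""
    return SyntheticCohortConfig(
        n_patients=6,
        n_controls=4,
        grid_shape=(48, 48, 24),
        wmh_volume_mean_sd=(900.0, 300.0),
        recording_duration_s=8.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def table_only_config():
    """Fast cohort for replicate suites: no volumes, no recordings."""
    return SyntheticCohortConfig(render_volumes=False, render_recordings=False, seed=0)


@pytest.fixture(scope="session")
def tissue_small():
    cfg = SyntheticCohortConfig(grid_shape=(48, 48, 24))
    return generate_tissue_volume(cfg)


@pytest.fixture(scope="session")
def atlas_small(tissue_small):
    return generate_atlas(tissue_small)


def reseed(config, seed):
    return dataclasses.replace(config, seed=seed)
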