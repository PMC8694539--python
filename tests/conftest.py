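import dataclasses

import numpy as np
import pytest

from hrca.synthgen import (
    CohortConfig,
    generate_cohort,
    generate_feature_table,
    study_replica_config,
)


@pytest.fixture(scope="session")
def null_feature_table():
    """Study-replica feature table with no material effect."""
    cfg = dataclasses.replace(study_replica_config(seed=11), effect_spec=[])
    return generate_feature_table(cfg)


@pytest.fixture(scope="session")
def small_signal_cohort():
    """A small signal-tier cohort (4 participants x 3 swallows/material)."""
    cfg = CohortConfig(n_participants=4, swallows_per_material=3, seed=7)
    segments, manifest = generate_cohort(cfg)
    return cfg, segments, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
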