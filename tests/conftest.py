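"""Shared fixtures: a small deterministic synthetic cohort and helpers."""

import numpy as np
import pytest

from gliorad import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    return CohortConfig(
        n_recurrence=10,
        n_necrosis=6,
        seed=123,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240615)
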