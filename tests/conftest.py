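"""Shared fixtures: parameter sets, reference walls, and small seeded cohorts.

Expensive cohort fits are session-scoped so the per-case inverse pipeline
runs once and is examined by several tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from lvmech import (
    ActiveParams,
    CohortConfig,
    ModalityDistortion,
    PassiveParams,
    ReducedWall,
    generate_cohort,
    run_cohort,
)


@pytest.fixture(scope="session")
def passive() -> PassiveParams:
    return PassiveParams(C=0.12)


@pytest.fixture(scope="session")
def active() -> ActiveParams:
    return ActiveParams()


@pytest.fixture(scope="session")
def wall() -> ReducedWall:
    """A mid-sized unloaded ventricular wall (cavity ~58 mL, wall ~107 mL)."""
    return ReducedWall(2.4, 3.4)


@pytest.fixture(scope="session")
def default_cohort():
    """The default seeded 7-case paired-modality cohort."""
    return generate_cohort(7, CohortConfig(), master_seed=0)


@pytest.fixture(scope="session")
def default_outcome(default_cohort):
    """Full inverse pipeline run on the default cohort."""
    return run_cohort(default_cohort)


@pytest.fixture(scope="session")
def recovery_cohort():
    """20 cases: one noiseless-identity record and one 2 mL-noise record each.

    The 'echo' slot carries the noiseless identity acquisition (160 samples,
    unit scales) used for exact parameter recovery; the 'mri' slot carries
    the 2 mL volume-noise acquisition used for the noisy regression check.
    """
    cfg = CohortConfig(
        mri=ModalityDistortion(1.0, 2.0, 1.0, 15),
        echo=ModalityDistortion(1.0, 0.0, 1.0, 160),
    )
    return generate_cohort(20, cfg, master_seed=11)


@pytest.fixture(scope="session")
def recovery_outcome(recovery_cohort):
    return run_cohort(recovery_cohort)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
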