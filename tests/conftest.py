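"""Shared fixtures: seeded synthetic runs reused across test modules.

The two expensive fixtures (the end-to-end profile-recovery pipeline and
the parental variant-recovery experiment) are session-scoped so the suite
pays for each exactly once.
"""

import numpy as np
import pytest

from hybridase.pipeline import run_pipeline
from hybridase.validation import (
    recovery_pipeline_config,
    variant_recovery_experiment,
)

#: fixed seeds for the session fixtures; chosen once, never tuned
RECOVERY_SEED = 11
DENSITY_SEED = 7


@pytest.fixture(scope="session")
def recovery_result():
    """End-to-end pipeline run under the profile-recovery conditions
    (200 genes, strong effects, >= ~100 informative reads per gene)."""
    return run_pipeline(recovery_pipeline_config(seed=RECOVERY_SEED))


@pytest.fixture(scope="session")
def variant_recovery():
    """Parental variant-recovery experiment at the published densities
    (0.92 shared SNPs/kb, 0.07 InDels/kb, 0.72 parental SNPs/gene) with
    ~30x parental coverage and 0.1 % base error."""
    return variant_recovery_experiment(seed=DENSITY_SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
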