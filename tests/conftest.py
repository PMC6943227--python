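import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from fmt_engraft import CohortSimSpec, StrainSimSpec, simulate_snv_cohort, simulate_species_cohort

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_cohort():
    """6-pair cohort with d=0.3, g=0.05, shared across read-only tests."""
    spec = CohortSimSpec(n_pairs=6, n_taxa=80, timepoints=(3, 7), seed=11)
    abundance, manifest, truth = simulate_species_cohort(spec)
    return abundance, manifest, truth


@pytest.fixture(scope="session")
def small_snv(small_cohort):
    _, manifest, _ = small_cohort
    spec = StrainSimSpec(n_species=4, positions_per_species=60, seed=12)
    return simulate_snv_cohort(spec, manifest)


def series(values, index=None):
    return pd.Series(values, index=index or [f"T{i}" for i in range(len(values))])
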