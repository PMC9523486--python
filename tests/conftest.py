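import numpy as np
import pytest

from tmbcat import fit_joint_model, scenario_presets, simulate_cohort
from tmbcat.data_model import Cohort


@pytest.fixture(scope="session")
def consistent_cohort():
    """One cohort from the consistent-direction scenario (seeded)."""
    cfg = scenario_presets("consistent")
    return simulate_cohort(cfg, seed=101)


@pytest.fixture(scope="session")
def consistent_fit(consistent_cohort):
    cohort, _ = consistent_cohort
    return fit_joint_model(cohort)


@pytest.fixture(scope="session")
def null_cohort():
    """Null-scenario cohort: no TMB effect, real patient heterogeneity."""
    cfg = scenario_presets("null")
    return simulate_cohort(cfg, seed=202)


@pytest.fixture(scope="session")
def null_fit(null_cohort):
    cohort, _ = null_cohort
    return fit_joint_model(cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def tiny_cohort():
    """Hand-built 6-patient cohort with distinct TMB values."""
    return Cohort.from_arrays(
        None,
        R=[1, 0, 1, 0, 0, 1],
        T=[3.0, 6.5, 12.0, 1.2, 8.8, 20.0],
        delta=[1, 1, 0, 1, 1, 0],
        tmb=[2.0, 4.5, 7.0, 9.5, 12.0, 18.0],
    )
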