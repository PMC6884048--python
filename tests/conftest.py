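import numpy as np
import pytest

from oxydose import GeneratorConfig, apply_exclusions, build_nested_subsets, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort shared by read-only tests."""
    cfg = GeneratorConfig(n_patients=1500, seed=42)
    admissions, blood_gas = generate_cohort(cfg)
    return cfg, admissions, blood_gas


@pytest.fixture(scope="session")
def nested_subsets(small_cohort):
    _, admissions, blood_gas = small_cohort
    cohort, log = apply_exclusions(admissions)
    subsets = build_nested_subsets(cohort, blood_gas)
    return cohort, log, subsets


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
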