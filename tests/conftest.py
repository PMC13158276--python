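import numpy as np
import pytest

from scintivur.phantom import PhantomConfig, generate_cohort, generate_patient


@pytest.fixture(scope="session")
def noise_free_config() -> PhantomConfig:
    return PhantomConfig(noise_model="none")


@pytest.fixture(scope="session")
def default_scan():
    """One noisy default-config scan with a severe left-sided defect."""
    return generate_patient(PhantomConfig(), 4, 0, patient_seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    """Shared 30-patient default cohort (scans + manifest)."""
    return generate_cohort(PhantomConfig(), 30, 0.5, seed=5)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
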