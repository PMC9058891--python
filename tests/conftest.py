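import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tie2response import BiomarkerSeries, GeneratorConfig, Measurement, simulate_cohort

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_series(days, concentrations, patient_id="P1", marker="TIE2"):
    return BiomarkerSeries(
        patient_id, marker,
        tuple(Measurement(d, c) for d, c in zip(days, concentrations)),
    )


@pytest.fixture(scope="session")
def default_cohort():
    """Moderate cohort at the generator's default study conditions."""
    return simulate_cohort(GeneratorConfig(n_patients=200, seed=11))


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Noise-free cohort with every patient progressing at a 42-day lead."""
    cfg = GeneratorConfig(
        n_patients=60, seed=5, noise_cv=0.0,
        fraction_progressing=1.0, p_vascular_rise=1.0, p_epithelial_rise=1.0,
        lead_choices_days=(42,),
    )
    return simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
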