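import dataclasses

import pytest

from neolos.cohort import Cohort, HealthScore, PatientRecord, Sex
from neolos.evaluation import load_reference_tables
from neolos.simulate import default_config, generate_cohort


@pytest.fixture(scope="session")
def reference() -> dict:
    return load_reference_tables()


@pytest.fixture
def make_record():
    """Factory for a valid control record; override any field."""

    def _make(**overrides) -> PatientRecord:
        base = dict(
            patient_id="p-001",
            cohort=Cohort.DEVELOPMENT,
            gestational_age_weeks=30.0,
            corrected_ga_weeks=32.0,
            birthweight_g=1400.0,
            sex=Sex.F,
            day_of_life=14,
            central_line=False,
            parenteral_nutrition=False,
            temp_min_c=36.5,
            temp_max_c=37.0,
            hr_max_bpm=160.0,
            glucose_max_mgdl=90.0,
            wbc_min=8000.0,
            wbc_max=12000.0,
            anc_min=2500.0,
            anc_max=4000.0,
            lymph_min=3000.0,
            platelets_min=250000.0,
            crp_max_mgdl=0.1,
            nlr_max=0.8,
            health_score_0h=HealthScore.HEALTHY,
            health_score_24h=HealthScore.HEALTHY,
            culture_positive=False,
            time_to_positivity_h=None,
            sepsis=False,
        )
        base.update(overrides)
        return PatientRecord(**base)

    return _make


@pytest.fixture(scope="session")
def cohort_5000():
    """One mid-size calibrated cohort, shared across tests."""
    cfg = dataclasses.replace(default_config(), n_total=5000, seed=42)
    return generate_cohort(cfg)
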