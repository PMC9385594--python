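import numpy as np
import pandas as pd
import pytest

import wtclung as w


@pytest.fixture(scope="session")
def toy_model():
    return w.load_bundled_model("toy")


@pytest.fixture(scope="session")
def plco_model():
    return w.load_bundled_model("plco2012")


@pytest.fixture(scope="session")
def imputed_cohort():
    """Synthetic cohort of 4,000 with complete risk-model inputs."""
    df = w.generate_cohort(w.GeneratorConfig(n=4000, seed=42))
    return w.impute_all(
        df, w.ImputationConfig(family_history_prevalence=0.12), seed=43)


@pytest.fixture(scope="session")
def analytic_cohort(imputed_cohort, toy_model):
    """Eligibility-filtered cohort with outcomes planted from the toy model."""
    obs = w.plant_outcomes_from_model(imputed_cohort, toy_model, seed=44)
    return w.apply_eligibility(obs)


def make_participants(rows: list[dict]) -> pd.DataFrame:
    """Build a schema-complete cohort frame from sparse row dicts."""
    defaults = {
        "id": None, "enrollment_date": "2003-01-01", "age_at_enrollment": 45.0,
        "sex": "male", "race_ethnicity": "nl_white", "education": "hs_grad",
        "bmi": 28.0, "copd": False, "fev1": 3.2, "fvc": 4.0,
        "smoking_status": "never", "cigarettes_per_day": 0.0,
        "smoking_duration": 0.0, "pack_years": 0.0, "years_since_quit": None,
        "family_history_lung_cancer": False, "prior_cancer": False,
        "wtc_exposure_level": "intermediate", "wtc_arrival_48h": True,
        "wtc_duration_gt60d": False,
        **{c: False for c in w.cohort.OCC_COLUMNS},
        "last_encounter_date": "2014-01-01", "lung_cancer": False,
        "lung_cancer_date": None,
    }
    out = []
    for i, row in enumerate(rows):
        rec = {**defaults, **row}
        if rec["id"] is None:
            rec["id"] = f"P{i:03d}"
        out.append(rec)
    df = pd.DataFrame(out)
    for c in ("enrollment_date", "last_encounter_date", "lung_cancer_date"):
        df[c] = pd.to_datetime(df[c])
    return df[list(w.cohort.COLUMNS)]
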