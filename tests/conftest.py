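from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from coolmatch import SimParams, build_analysis_table, generate_cohort
from coolmatch.derive import AnalysisTable


@pytest.fixture(scope="session")
def small_cohort():
    """A confounded synthetic cohort small enough for per-test reuse."""
    params = SimParams(n_babies=800, seed=42)
    infants, days, truth = generate_cohort(params)
    return params, infants, days, truth


@pytest.fixture(scope="session")
def small_analysis(small_cohort) -> AnalysisTable:
    _, infants, days, _ = small_cohort
    return build_analysis_table(infants, days)


def make_day_rows(infant_id: str, **columns) -> pd.DataFrame:
    """Build a day table for one baby from per-day column lists.

    Columns are aligned on 'day' (defaults to 1..n); unspecified flags are 0.
    """
    n = len(next(iter(columns.values())))
    base = {
        "infant_id": infant_id,
        "day": columns.pop("day", list(range(1, n + 1))),
        "cooled": [0.0] * n,
        "enteral_fed": [0.0] * n,
        "milk_type": ["none"] * n,
        "nil_by_mouth": [0.0] * n,
        "antibiotics": [0.0] * n,
        "parenteral_nutrition": [0.0] * n,
        "central_line": [0.0] * n,
        "breastfed_at_breast": [0.0] * n,
    }
    base.update(columns)
    return pd.DataFrame(base)


def make_infant(infant_id: str = "B1", **overrides) -> dict:
    """A minimal plausible infant record for hand-built derivation tests."""
    rec = {
        "infant_id": infant_id,
        "birth_year": 2013,
        "gestational_age_weeks": 39.0,
        "birthweight_g": 3400.0,
        "sex": "female",
        "multiple_birth": 0.0,
        "maternal_age": 30.0,
        "membrane_rupture_hours": 4.0,
        "maternal_fever": 0.0,
        "suspected_chorioamnionitis": 0.0,
        "maternal_smoking": 0.0,
        "maternal_ethnicity": "white",
        "deprivation_decile": 5.0,
        "maternal_hypothyroidism": 0.0,
        "maternal_diabetes": 0.0,
        "caesarean_delivery": 0.0,
        "primiparous": 1.0,
        "apgar_1": 3.0,
        "apgar_5": 6.0,
        "chest_compressions": 0.0,
        "resus_drugs": 0.0,
        "intubated_at_resus": 1.0,
        "cord_arterial_ph": 6.95,
        "time_to_first_breath_min": 5.0,
        "admission_mean_bp": 45.0,
        "admission_glucose": 4.0,
        "admission_heart_rate": 120.0,
        "admission_spo2": 96.0,
        "admission_temperature": 35.8,
        "early_onset_culture_positive": 0.0,
        "inotropes_day1": 0.0,
        "mechanical_ventilation_day1": 1.0,
        "nitric_oxide_day1": 0.0,
        "postnatal_transfer_24h": 0.0,
        "network": "N01",
        "parenteral_nutrition_day1": 0.0,
        "death_flag": 0.0,
        "death_day": np.nan,
        "discharge_day": 12.0,
        "nec_diagnosis_recorded": 0.0,
        "severe_nec_confirmed": 0.0,
        "blood_cultures": "",
        "breastfeeding_at_discharge": 1.0,
        "discharge_weight_g": 3500.0,
        "hypoglycaemia_recorded": 0.0,
    }
    rec.update(overrides)
    return rec


def make_infants(records: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(records)
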