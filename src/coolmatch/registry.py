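"""Covariate registry: the background variables entering the propensity model.

The registry is the single place that names the covariate columns of
``infants.csv`` and states their type, so that cohort derivation, the
propensity model, and balance reporting all agree on the model matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence


@dataclass(frozen=True)
class Covariate:
    """One background variable.

    kind is one of ``continuous``, ``binary`` (0/1 column) or
    ``categorical`` (string column; ``levels[0]`` is the reference level,
    which also absorbs imputed missing values).
    """

    name: str
    kind: str
    levels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary", "categorical"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if self.kind == "categorical" and len(self.levels) < 2:
            raise ValueError(f"categorical covariate {self.name} needs >=2 levels")


ETHNICITY_LEVELS = ("white", "asian", "black", "other")
NETWORKS = tuple(f"N{i:02d}" for i in range(1, 11))

#: Demographics, maternal factors, birth factors, admission condition,
#: early-onset infection, day-1 treatments and organisational factors.
DEFAULT_REGISTRY: tuple[Covariate, ...] = (
    Covariate("gestational_age_weeks", "continuous"),
    Covariate("birthweight_g", "continuous"),
    Covariate("sex", "categorical", ("male", "female")),
    Covariate("multiple_birth", "binary"),
    Covariate("maternal_age", "continuous"),
    Covariate("membrane_rupture_hours", "continuous"),
    Covariate("maternal_fever", "binary"),
    Covariate("suspected_chorioamnionitis", "binary"),
    Covariate("maternal_smoking", "binary"),
    Covariate("maternal_ethnicity", "categorical", ETHNICITY_LEVELS),
    Covariate("deprivation_decile", "continuous"),
    Covariate("maternal_hypothyroidism", "binary"),
    Covariate("maternal_diabetes", "binary"),
    Covariate("caesarean_delivery", "binary"),
    Covariate("primiparous", "binary"),
    Covariate("apgar_1", "continuous"),
    Covariate("apgar_5", "continuous"),
    Covariate("chest_compressions", "binary"),
    Covariate("resus_drugs", "binary"),
    Covariate("intubated_at_resus", "binary"),
    Covariate("cord_arterial_ph", "continuous"),
    Covariate("time_to_first_breath_min", "continuous"),
    Covariate("admission_mean_bp", "continuous"),
    Covariate("admission_glucose", "continuous"),
    Covariate("admission_heart_rate", "continuous"),
    Covariate("admission_spo2", "continuous"),
    Covariate("admission_temperature", "continuous"),
    Covariate("early_onset_culture_positive", "binary"),
    Covariate("inotropes_day1", "binary"),
    Covariate("mechanical_ventilation_day1", "binary"),
    Covariate("nitric_oxide_day1", "binary"),
    Covariate("postnatal_transfer_24h", "binary"),
    Covariate("network", "categorical", NETWORKS),
)

#: Covariate added to the propensity model by the parenteral-nutrition
#: sensitivity analysis.
PN_DAY1_COVARIATE = Covariate("parenteral_nutrition_day1", "binary")

#: Non-covariate infant columns (identifiers and outcome source fields).
INFANT_EXTRA_COLUMNS: tuple[str, ...] = (
    "infant_id",
    "birth_year",
    "death_flag",
    "death_day",
    "discharge_day",
    "nec_diagnosis_recorded",
    "severe_nec_confirmed",
    "blood_cultures",
    "breastfeeding_at_discharge",
    "discharge_weight_g",
    "hypoglycaemia_recorded",
)

DAY_COLUMNS: tuple[str, ...] = (
    "infant_id",
    "day",
    "cooled",
    "enteral_fed",
    "milk_type",
    "nil_by_mouth",
    "antibiotics",
    "parenteral_nutrition",
    "central_line",
    "breastfed_at_breast",
)


def registry_names(registry: Sequence[Covariate]) -> list[str]:
    return [c.name for c in registry]


def infant_columns(registry: Sequence[Covariate] = DEFAULT_REGISTRY) -> list[str]:
    """Full column list of infants.csv in canonical order."""
    cols = list(INFANT_EXTRA_COLUMNS[:2])  # infant_id, birth_year
    cols += registry_names(registry)
    cols.append(PN_DAY1_COVARIATE.name)
    cols += INFANT_EXTRA_COLUMNS[2:]
    return cols
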