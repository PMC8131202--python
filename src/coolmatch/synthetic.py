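"""Synthetic NNRD-like cohort generator.

Emulates the structure of a national neonatal database for babies treated
with whole-body therapeutic hypothermia: one infant-level table (background
covariates and outcome source fields) and one infant-day table (cooling,
feeding, antibiotics, nil-by-mouth, line flags).  A single latent severity
score ``z`` per baby drives the recorded markers of illness (low Apgar, low
cord pH, inotropes, ventilation, ...) and the outcome risks; the decision to
feed during cooling depends on severity as seen through the *recorded*
covariates, so sicker babies are both less likely to be fed and more likely
to die or be treated for infection.  Known true effects can be injected per
outcome, giving downstream stages a testable ground truth.

Outcome flags are realised in the day-level data (antibiotic runs, nil by
mouth, culture days) so that the pragmatic outcome definitions derived
downstream agree exactly with the generator's ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .growth import GrowthReference, synthetic_reference
from .registry import DAY_COLUMNS, ETHNICITY_LEVELS, NETWORKS, infant_columns

__all__ = [
    "SimParams",
    "GroundTruth",
    "generate_cohort",
    "write_fixture",
    "read_infants",
    "read_days",
    "BINARY_OUTCOMES",
    "CONTINUOUS_OUTCOMES",
    "OUTCOME_NAMES",
]

BINARY_OUTCOMES = (
    "pragmatic_nec",
    "culture_positive_late_onset",
    "pragmatic_late_onset_infection",
    "hypoglycaemia",
    "survival_to_discharge",
    "breastfeeding_at_discharge",
)
CONTINUOUS_OUTCOMES = (
    "length_of_stay",
    "onset_of_breastfeeding",
    "first_maternal_milk_day",
    "parenteral_nutrition_days",
    "central_line_days",
    "weight_sd_score",
)
OUTCOME_NAMES = BINARY_OUTCOMES + CONTINUOUS_OUTCOMES

#: Marginal outcome incidences the generator is calibrated to (cohort-wide,
#: fed and unfed together, under the default null effects).
DEFAULT_BASE_RATES: dict[str, float] = {
    "pragmatic_nec": 0.011,
    "culture_positive_late_onset": 0.005,
    "pragmatic_late_onset_infection": 0.259,
    "hypoglycaemia": 0.200,
    "survival_to_discharge": 0.903,
    "breastfeeding_at_discharge": 0.462,
}

#: MCAR missingness proportions per recorded covariate.
DEFAULT_MISSINGNESS: dict[str, float] = {
    "cord_arterial_ph": 0.28,
    "maternal_age": 0.05,
    "membrane_rupture_hours": 0.20,
    "maternal_fever": 0.12,
    "suspected_chorioamnionitis": 0.18,
    "maternal_smoking": 0.14,
    "maternal_ethnicity": 0.16,
    "deprivation_decile": 0.15,
    "maternal_hypothyroidism": 0.07,
    "maternal_diabetes": 0.05,
    "caesarean_delivery": 0.04,
    "primiparous": 0.06,
    "apgar_1": 0.08,
    "apgar_5": 0.08,
    "time_to_first_breath_min": 0.18,
    "admission_mean_bp": 0.15,
    "admission_glucose": 0.12,
    "admission_heart_rate": 0.10,
    "admission_spo2": 0.10,
    "admission_temperature": 0.12,
    "mechanical_ventilation_day1": 0.03,
    "inotropes_day1": 0.04,
}

# Weights of the recorded-severity index used for the feeding decision;
# signs follow clinical direction (sicker => higher index => less likely fed).
_SEVERITY_WEIGHTS: dict[str, float] = {
    "apgar_1": -0.8,
    "apgar_5": -0.8,
    "cord_arterial_ph": -0.6,
    "chest_compressions": 0.5,
    "resus_drugs": 0.4,
    "intubated_at_resus": 0.4,
    "time_to_first_breath_min": 0.4,
    "admission_mean_bp": -0.5,
    "admission_spo2": -0.4,
    "admission_heart_rate": 0.35,
    "admission_temperature": -0.3,
    "admission_glucose": 0.3,
    "inotropes_day1": 0.6,
    "mechanical_ventilation_day1": 0.5,
    "nitric_oxide_day1": 0.2,
    "caesarean_delivery": 0.2,
}


def _check_proportion(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass(frozen=True)
class SimParams:
    """Study conditions for one synthetic cohort."""

    n_babies: int = 6030
    year_range: tuple[int, int] = (2010, 2017)
    p_fed_target: float = 0.311
    confounding_strength: float = 1.0
    true_effects: Mapping[str, float] = field(default_factory=dict)
    missingness: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_MISSINGNESS))
    outcome_base_rates: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BASE_RATES))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_babies < 2:
            raise ValueError(f"n_babies must be >= 2, got {self.n_babies}")
        lo, hi = self.year_range
        if not (2008 <= lo <= hi <= 2017):
            raise ValueError(f"year_range must lie within 2008-2017, got {self.year_range}")
        _check_proportion("p_fed_target", self.p_fed_target)
        if self.confounding_strength < 0:
            raise ValueError("confounding_strength must be >= 0")
        for k, v in self.missingness.items():
            _check_proportion(f"missingness[{k}]", v)
        for k, v in self.outcome_base_rates.items():
            _check_proportion(f"outcome_base_rates[{k}]", v)
        unknown = set(self.true_effects) - set(OUTCOME_NAMES)
        if unknown:
            raise ValueError(f"unknown outcome(s) in true_effects: {sorted(unknown)}")
        unknown = set(self.outcome_base_rates) - set(BINARY_OUTCOMES)
        if unknown:
            raise ValueError(f"outcome_base_rates only apply to binary outcomes: {sorted(unknown)}")

    def effect(self, outcome: str) -> float:
        return float(self.true_effects.get(outcome, 0.0))

    def base_rate(self, outcome: str) -> float:
        return float(self.outcome_base_rates.get(outcome, DEFAULT_BASE_RATES[outcome]))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["year_range"] = list(self.year_range)
        d["true_effects"] = dict(self.true_effects)
        d["missingness"] = dict(self.missingness)
        d["outcome_base_rates"] = dict(self.outcome_base_rates)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimParams":
        d = dict(d)
        d["year_range"] = tuple(d["year_range"])
        return cls(**d)


@dataclass
class GroundTruth:
    """What the generator actually did: effects, links and per-baby severity."""

    params: SimParams
    true_effects: dict[str, float]
    alpha_fed: float
    intercepts: dict[str, float]
    severity: pd.Series  # latent z per infant_id
    severity_index: pd.Series  # recorded-covariate index driving feeding
    fed: pd.Series  # ground-truth exposure per infant_id
    eligible: pd.Series  # gestational age >= 36 weeks

    def fed_probability(self, index_values: np.ndarray) -> np.ndarray:
        c = self.params.confounding_strength
        return expit(self.alpha_fed - c * np.asarray(index_values, float))

    def outcome_probability(self, outcome: str, z, fed) -> np.ndarray:
        """P(derived outcome | z, fed) under the generating model.

        For pragmatic late-onset infection this includes the contribution of
        NEC babies, whose antibiotic/nil-by-mouth run also satisfies the
        late-onset run definition.
        """
        z = np.asarray(z, float)
        fed = np.asarray(fed, float)
        c = self.params.confounding_strength
        eff = self.true_effects

        def p(name: str, z_coef: float) -> np.ndarray:
            return expit(self.intercepts[name] + z_coef * z + eff.get(name, 0.0) * fed)

        if outcome == "pragmatic_late_onset_infection":
            p_loi = p("pragmatic_late_onset_infection", c)
            p_nec = p("pragmatic_nec", c)
            return 1.0 - (1.0 - p_loi) * (1.0 - p_nec)
        if outcome in ("pragmatic_nec", "culture_positive_late_onset", "hypoglycaemia"):
            return p(outcome, c)
        if outcome == "survival_to_discharge":
            return p(outcome, -c)
        if outcome == "breastfeeding_at_discharge":
            return p("survival_to_discharge", -c) * p(outcome, -0.5 * c)
        raise KeyError(f"no closed-form probability for outcome {outcome!r}")


def _solve_intercept(mean_fn, target: float) -> float:
    """Intercept b with mean_fn(b) == target; mean_fn increasing in b."""
    return float(brentq(lambda b: mean_fn(b) - target, -25.0, 25.0, xtol=1e-12))


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def generate_cohort(
    params: SimParams, growth_ref: GrowthReference | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (infants, infant_days, ground_truth) for the given conditions.

    Identical params (including seed) yield byte-identical tables.
    """
    if growth_ref is None:
        growth_ref = synthetic_reference()
    rng = np.random.default_rng(params.seed)
    n = params.n_babies
    c = params.confounding_strength

    z = rng.standard_normal(n)
    ids = np.array([f"B{i:06d}" for i in range(1, n + 1)])

    # --- background covariates (true values, before missingness) ---------
    cov: dict[str, np.ndarray] = {}
    ga = np.clip(rng.normal(39.5, 1.5, n), 34.5, 43.0)
    cov["gestational_age_weeks"] = np.round(ga - 0.08 * z, 1)
    cov["birthweight_g"] = np.round(
        np.clip(3400 + 170 * (cov["gestational_age_weeks"] - 39.5) - 40 * z + rng.normal(0, 540, n), 1500, 6000)
    )
    sex = np.where(rng.random(n) < 0.55, "male", "female")
    cov["multiple_birth"] = (rng.random(n) < 0.03).astype(float)
    cov["maternal_age"] = np.round(np.clip(rng.normal(30.5, 5.8, n), 14, 52))
    cov["membrane_rupture_hours"] = np.round(np.exp(rng.normal(1.2, 1.1, n)), 1)
    cov["maternal_fever"] = (rng.random(n) < expit(logit(0.05) + 0.1 * z)).astype(float)
    cov["suspected_chorioamnionitis"] = (rng.random(n) < expit(logit(0.14) + 0.2 * z)).astype(float)
    cov["maternal_smoking"] = (rng.random(n) < 0.14).astype(float)
    eth = rng.choice(len(ETHNICITY_LEVELS), size=n, p=[0.77, 0.125, 0.08, 0.025])
    cov["deprivation_decile"] = rng.integers(1, 11, n).astype(float)
    cov["maternal_hypothyroidism"] = (rng.random(n) < 0.012).astype(float)
    cov["maternal_diabetes"] = (rng.random(n) < 0.042).astype(float)
    cov["caesarean_delivery"] = (rng.random(n) < expit(logit(0.47) + 0.35 * z)).astype(float)
    cov["primiparous"] = (rng.random(n) < expit(logit(0.53) + 0.15 * z)).astype(float)
    cov["apgar_1"] = np.clip(np.round(rng.normal(3.6 - 1.5 * z, 1.8)), 0, 10)
    cov["apgar_5"] = np.clip(np.round(rng.normal(5.6 - 1.5 * z, 1.8)), 0, 10)
    cov["chest_compressions"] = (rng.random(n) < expit(logit(0.37) + 0.9 * z)).astype(float)
    cov["resus_drugs"] = (rng.random(n) < expit(logit(0.15) + 0.9 * z)).astype(float)
    cov["intubated_at_resus"] = (rng.random(n) < expit(logit(0.64) + 0.8 * z)).astype(float)
    cov["cord_arterial_ph"] = np.round(6.977 - 0.099 * z + rng.normal(0, 0.132, n), 3)
    cov["time_to_first_breath_min"] = np.round(np.exp(np.log(5.0) + 0.35 * z + rng.normal(0, 0.5, n)), 1)
    cov["admission_mean_bp"] = np.round(46 - 4 * z + rng.normal(0, 6, n), 1)
    cov["admission_glucose"] = np.round(np.clip(4.2 + 0.5 * z + rng.normal(0, 1.3, n), 0.3, 25), 1)
    cov["admission_heart_rate"] = np.round(125 + 6 * z + rng.normal(0, 13, n))
    cov["admission_spo2"] = np.round(np.clip(96 - 1.5 * z + rng.normal(0, 2.5, n), 40, 100))
    cov["admission_temperature"] = np.round(35.8 - 0.3 * z + rng.normal(0, 0.7, n), 1)
    cov["early_onset_culture_positive"] = (rng.random(n) < expit(logit(0.009) + 0.3 * z)).astype(float)
    cov["inotropes_day1"] = (rng.random(n) < expit(logit(0.25) + 1.1 * z)).astype(float)
    cov["mechanical_ventilation_day1"] = (rng.random(n) < expit(logit(0.80) + 1.0 * z)).astype(float)
    cov["nitric_oxide_day1"] = (rng.random(n) < expit(logit(0.04) + 0.9 * z)).astype(float)
    cov["postnatal_transfer_24h"] = (rng.random(n) < expit(logit(0.40) + 0.2 * z)).astype(float)
    network = rng.choice(len(NETWORKS), size=n)
    birth_year = rng.integers(params.year_range[0], params.year_range[1] + 1, n)

    # --- MCAR missingness on the recorded covariates ---------------------
    recorded = {k: v.copy() for k, v in cov.items()}
    ethnicity_rec = np.array(ETHNICITY_LEVELS, object)[eth]
    # sorted so the draw order (hence the output) is independent of dict order
    for name in sorted(params.missingness):
        frac = params.missingness[name]
        if frac == 0:
            continue
        mask = rng.random(n) < frac
        if name == "maternal_ethnicity":
            ethnicity_rec = ethnicity_rec.copy()
            ethnicity_rec[mask] = None
        elif name in recorded:
            recorded[name][mask] = np.nan

    # --- feeding decision from recorded severity --------------------------
    # Clinicians act on the charted values: the index is a fixed linear
    # combination of the recorded covariates (missing entries at the mean),
    # so feeding is ignorable given the recorded background variables.
    s = np.zeros(n)
    for name, w in _SEVERITY_WEIGHTS.items():
        x = recorded[name]
        filled = np.where(np.isnan(x), np.nanmean(x), x)
        s += w * _standardize(filled)
    s = _standardize(s)
    alpha_fed = _solve_intercept(lambda b: expit(b - c * s).mean(), params.p_fed_target)
    fed = rng.random(n) < expit(alpha_fed - c * s)
    fed_f = fed.astype(float)

    # --- binary outcome flags (intercepts calibrated to marginal targets) -
    eff = {k: params.effect(k) for k in OUTCOME_NAMES}
    intercepts: dict[str, float] = {}

    def lin(b, z_coef, e):
        return expit(b + z_coef * z + e * fed_f)

    intercepts["survival_to_discharge"] = _solve_intercept(
        lambda b: lin(b, -c, eff["survival_to_discharge"]).mean(), params.base_rate("survival_to_discharge")
    )
    p_surv = lin(intercepts["survival_to_discharge"], -c, eff["survival_to_discharge"])
    survived = rng.random(n) < p_surv

    intercepts["pragmatic_nec"] = _solve_intercept(
        lambda b: lin(b, c, eff["pragmatic_nec"]).mean(), params.base_rate("pragmatic_nec")
    )
    p_nec = lin(intercepts["pragmatic_nec"], c, eff["pragmatic_nec"])
    nec = rng.random(n) < p_nec

    # NEC babies' antibiotic+NBM run also satisfies the late-onset run rule,
    # so calibrate the infection intercept on the union probability.
    def loi_mean(b):
        return (1 - (1 - lin(b, c, eff["pragmatic_late_onset_infection"])) * (1 - p_nec)).mean()

    intercepts["pragmatic_late_onset_infection"] = _solve_intercept(
        loi_mean, params.base_rate("pragmatic_late_onset_infection")
    )
    loi = rng.random(n) < lin(intercepts["pragmatic_late_onset_infection"], c, eff["pragmatic_late_onset_infection"])

    intercepts["culture_positive_late_onset"] = _solve_intercept(
        lambda b: lin(b, c, eff["culture_positive_late_onset"]).mean(),
        params.base_rate("culture_positive_late_onset"),
    )
    culture_pos = rng.random(n) < lin(intercepts["culture_positive_late_onset"], c, eff["culture_positive_late_onset"])

    intercepts["hypoglycaemia"] = _solve_intercept(
        lambda b: lin(b, c, eff["hypoglycaemia"]).mean(), params.base_rate("hypoglycaemia")
    )
    hypo = rng.random(n) < lin(intercepts["hypoglycaemia"], c, eff["hypoglycaemia"])

    intercepts["breastfeeding_at_discharge"] = _solve_intercept(
        lambda b: (p_surv * lin(b, -0.5 * c, eff["breastfeeding_at_discharge"])).mean(),
        params.base_rate("breastfeeding_at_discharge"),
    )
    bf = survived & (
        rng.random(n) < lin(intercepts["breastfeeding_at_discharge"], -0.5 * c, eff["breastfeeding_at_discharge"])
    )

    # --- stay structure ---------------------------------------------------
    los = np.maximum(
        3, np.round(np.exp(np.log(10.0) + 0.18 * c * z + eff["length_of_stay"] * fed_f + rng.normal(0, 0.42, n)))
    ).astype(int)
    death_day = np.where(~survived, 3 + rng.poisson(2.0, n), 0)

    # qualifying antibiotic runs (start day >= 5 keeps a clear gap after any
    # early course ending day <= 3, so run starts are unambiguous)
    run_start = rng.integers(5, 8, n)
    run_len = 5 + rng.poisson(1.0, n)
    run_end = run_start + run_len - 1
    has_late_run = loi | nec
    nbm_run = nec  # antibiotics AND nil-by-mouth during the run

    culture_day = rng.integers(4, 9, n)

    onset_noise = rng.normal(0, 0.25, n)
    onset = np.clip(
        np.round(np.exp(np.log(6.9) + 0.05 * c * z + onset_noise) + eff["onset_of_breastfeeding"] * fed_f), 2, 60
    ).astype(int)

    has_early_abx = rng.random(n) < 0.75
    early_len = np.where(rng.random(n) < 0.4, 2, 3)

    pn_flag = rng.random(n) < expit(logit(0.40) + 0.3 * c * z)
    pn_days = np.where(
        pn_flag,
        np.clip(np.round(np.exp(np.log(3.0) + 0.2 * c * z + rng.normal(0, 0.4, n)) + eff["parenteral_nutrition_days"] * fed_f), 1, 60),
        0,
    ).astype(int)
    cl_flag = rng.random(n) < 0.93
    cl_days = np.where(
        cl_flag,
        np.clip(np.round(np.exp(np.log(5.0) + 0.12 * c * z + rng.normal(0, 0.35, n)) + eff["central_line_days"] * fed_f), 1, 90),
        0,
    ).astype(int)

    # the stay must contain every realised event
    min_stay = np.maximum.reduce(
        [
            np.full(n, 3),
            np.where(has_late_run, run_end, 0),
            np.where(culture_pos, culture_day, 0),
            np.where(bf, onset + 1, 0),
            pn_days,
            cl_days,
        ]
    )
    death_day = np.where(~survived, np.maximum(death_day, min_stay), 0)
    los = np.where(survived, np.maximum(los, min_stay), death_day)
    onset = np.minimum(onset, los)

    # feeding pattern: fed babies start on a cooling day, unfed from day >= 4
    first_fed = np.where(fed, rng.choice([1, 2, 3], size=n, p=[0.2, 0.4, 0.4]), 4 + rng.geometric(0.5, n) - 1)
    primary_milk = rng.choice(["maternal", "donor", "formula"], size=n, p=[0.72, 0.08, 0.20])

    day2_cooled_missing = (rng.random(n) < 0.05) & survived

    # --- build the day table (vectorised) ---------------------------------
    total = int(los.sum())
    rep = np.repeat(np.arange(n), los)
    offsets = np.repeat(np.cumsum(los) - los, los)
    day = (np.arange(total) - offsets + 1).astype(int)

    def bcast(x):
        return np.repeat(x, los)

    cooled = (day <= 3).astype(float)
    cooled[(day == 2) & bcast(day2_cooled_missing)] = np.nan

    in_cooling = day <= 3
    fed_b = bcast(fed)
    extra_fed = rng.random(total) < 0.75
    enteral = np.where(
        in_cooling & fed_b,
        (day == bcast(first_fed)) | ((day > bcast(first_fed)) & extra_fed),
        day >= bcast(first_fed),
    ).astype(float)
    # NEC / qualifying-run days: antibiotics, and nil-by-mouth when the run
    # defines pragmatic NEC
    in_run = bcast(has_late_run) & (day >= bcast(run_start)) & (day <= bcast(run_end))
    nbm_forced = bcast(nbm_run) & in_run
    enteral[nbm_forced] = 0.0
    # sporadic missing feeding cells
    feed_missing = rng.random(total) < 0.02
    enteral[feed_missing] = np.nan

    nbm = 1.0 - enteral  # inherits NaN where feeding is missing
    nbm[nbm_forced] = 1.0

    early = bcast(has_early_abx) & (day <= bcast(early_len))
    abx = (early | in_run).astype(float)

    milk = np.where(enteral == 1.0, bcast(primary_milk), "none").astype(object)
    milk[np.isnan(enteral)] = None

    pn = (day <= bcast(pn_days)).astype(float)
    cl = (day <= bcast(cl_days)).astype(float)

    bfd = (bcast(bf) & (day >= bcast(onset))).astype(float)
    bfd[rng.random(total) < 0.05] = np.nan

    days_df = pd.DataFrame(
        {
            "infant_id": bcast(ids),
            "day": day,
            "cooled": cooled,
            "enteral_fed": enteral,
            "milk_type": milk,
            "nil_by_mouth": nbm,
            "antibiotics": abx,
            "parenteral_nutrition": pn,
            "central_line": cl,
            "breastfed_at_breast": bfd,
        },
        columns=list(DAY_COLUMNS),
    )

    # --- infant table ------------------------------------------------------
    cultures = []
    early_pos = cov["early_onset_culture_positive"] == 1.0
    neg_culture = rng.random(n) < 0.3
    neg_day = rng.integers(1, 7, n)
    early_day = rng.integers(1, 4, n)
    for i in range(n):
        entries = []
        if early_pos[i]:
            entries.append(f"{early_day[i]}:1")
        if culture_pos[i]:
            entries.append(f"{culture_day[i]}:1")
        if neg_culture[i]:
            entries.append(f"{min(neg_day[i], los[i])}:0")
        cultures.append(";".join(entries))

    pma = cov["gestational_age_weeks"] + (los - 1) / 7.0
    wz = -0.6 - 0.15 * c * z + eff["weight_sd_score"] * fed_f + rng.normal(0, 1.05, n)
    discharge_weight = np.round(growth_ref.mean_g(pma, sex) + wz * growth_ref.sd_g(pma, sex))
    discharge_weight[~survived] = np.nan
    discharge_weight[rng.random(n) < 0.05] = np.nan

    bf_recorded = bf.astype(float)
    bf_recorded[rng.random(n) < 0.04] = np.nan

    severe_nec = nec & (rng.random(n) < 0.1)

    infants = pd.DataFrame({"infant_id": ids, "birth_year": birth_year})
    for name in recorded:
        infants[name] = recorded[name]
    infants["sex"] = sex
    infants["maternal_ethnicity"] = ethnicity_rec
    infants["network"] = np.array(NETWORKS, object)[network]
    infants["parenteral_nutrition_day1"] = (pn_days >= 1).astype(float)
    infants["death_flag"] = (~survived).astype(float)
    infants["death_day"] = np.where(~survived, death_day, np.nan)
    infants["discharge_day"] = los
    infants["nec_diagnosis_recorded"] = nec.astype(float)
    infants["severe_nec_confirmed"] = severe_nec.astype(float)
    infants["blood_cultures"] = cultures
    infants["breastfeeding_at_discharge"] = bf_recorded
    infants["discharge_weight_g"] = discharge_weight
    infants["hypoglycaemia_recorded"] = hypo.astype(float)
    infants = infants[infant_columns()]

    truth = GroundTruth(
        params=params,
        true_effects=eff,
        alpha_fed=alpha_fed,
        intercepts=intercepts,
        severity=pd.Series(z, index=ids, name="z"),
        severity_index=pd.Series(s, index=ids, name="severity_index"),
        fed=pd.Series(fed, index=ids, name="fed"),
        eligible=pd.Series(cov["gestational_age_weeks"] >= 36, index=ids, name="eligible"),
    )
    return infants, days_df, truth


# --- fixture I/O ----------------------------------------------------------


def write_fixture(infants: pd.DataFrame, days: pd.DataFrame, truth: GroundTruth | None, path) -> dict[str, Path]:
    """Write infants.csv / infant_days.csv (and ground_truth.json) under path.

    Every infant must have at least one day row; violations raise naming the
    first offending baby.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with_days = set(days["infant_id"].unique())
    missing = [i for i in infants["infant_id"] if i not in with_days]
    if missing:
        raise ValueError(f"infant {missing[0]} has an empty day table")
    out = {
        "infants": path / "infants.csv",
        "infant_days": path / "infant_days.csv",
    }
    infants.to_csv(out["infants"], index=False)
    days.to_csv(out["infant_days"], index=False)
    if truth is not None:
        out["ground_truth"] = path / "ground_truth.json"
        payload = {
            "params": truth.params.to_dict(),
            "true_effects": truth.true_effects,
            "alpha_fed": truth.alpha_fed,
            "intercepts": truth.intercepts,
        }
        out["ground_truth"].write_text(json.dumps(payload, indent=2, sort_keys=True))
    return out


def read_infants(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"infant_id": str, "sex": str, "maternal_ethnicity": str, "network": str, "blood_cultures": str})
    df["blood_cultures"] = df["blood_cultures"].fillna("")
    return df


def read_days(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"infant_id": str, "milk_type": str})
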