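"""Cohort derivation: eligibility, exposure, outcome definitions, covariates.

Turns the raw infant and infant-day tables into the per-baby analysis table:
one row per eligible baby with an exposure label (fed / unfed during
cooling), the expanded covariate matrix used by the propensity model (mean /
reference-category imputation plus a missing indicator per covariate with any
missingness), the exact-matching bands (birth-year band, cord-pH band) and
every outcome.

Day 1 is the day of birth throughout.  An antibiotic run is a maximal block
of consecutive calendar days on which antibiotics are recorded as given; a
day with antibiotics absent or missing (including a missing day row) breaks
the run, and a run "commences" on its first day.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .growth import GrowthReference, synthetic_reference
from .registry import Covariate, DEFAULT_REGISTRY, PN_DAY1_COVARIATE

__all__ = [
    "AnalysisTable",
    "impute_day2_cooling",
    "assess_eligibility",
    "classify_exposure",
    "infants_with_qualifying_run",
    "pragmatic_nec",
    "pragmatic_late_onset_infection",
    "culture_positive_late_onset",
    "parse_blood_cultures",
    "derive_secondary_outcomes",
    "year_band",
    "ph_band",
    "build_analysis_table",
    "OUTCOME_COLUMNS",
]

YEAR_BANDS = {2010: "2010-11", 2011: "2010-11", 2012: "2012-13", 2013: "2012-13",
              2014: "2014-15", 2015: "2014-15", 2016: "2016-17", 2017: "2016-17"}
PH_BANDS = ("lt6.9", "6.9to7.0", "gt7.0", "missing")

OUTCOME_COLUMNS = (
    "pragmatic_nec",
    "culture_positive_late_onset",
    "pragmatic_late_onset_infection",
    "hypoglycaemia",
    "survival_to_discharge",
    "breastfeeding_at_discharge",
    "length_of_stay",
    "onset_of_breastfeeding",
    "first_maternal_milk_day",
    "parenteral_nutrition_days",
    "central_line_days",
    "weight_sd_score",
)


@dataclass
class AnalysisTable:
    """Derived analysis table plus the bookkeeping around it."""

    df: pd.DataFrame
    covariate_columns: list[str]
    column_kinds: dict[str, str]  # covariate column -> binary | continuous
    exclusions: list[dict] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.df)


def impute_day2_cooling(days: pd.DataFrame, infants: pd.DataFrame | None = None) -> pd.DataFrame:
    """Fill missing day-2 cooling when days 1 and 3 were both cooled.

    Applies only to babies not recorded as dying during cooling (death on or
    before day 3); no other cell is altered.
    """
    days = days.copy()
    wide = days.pivot_table(index="infant_id", columns="day", values="cooled", aggfunc="first")
    for d in (1, 2, 3):
        if d not in wide.columns:
            wide[d] = np.nan
    target = wide.index[(wide[1] == 1) & (wide[3] == 1) & (wide[2].isna())]
    if infants is not None:
        died_cooling = infants.loc[
            (infants["death_flag"] == 1) & (infants["death_day"] <= 3), "infant_id"
        ]
        target = target.difference(pd.Index(died_cooling))
    mask = days["infant_id"].isin(target) & (days["day"] == 2) & days["cooled"].isna()
    days.loc[mask, "cooled"] = 1.0
    return days


def _cooling_summary(days: pd.DataFrame) -> pd.DataFrame:
    cooled = days[days["cooled"] == 1]
    return pd.DataFrame(
        {
            "cooled_days": cooled.groupby("infant_id")["day"].size(),
            "last_cooled_day": cooled.groupby("infant_id")["day"].max(),
        }
    )


def assess_eligibility(infants: pd.DataFrame, days: pd.DataFrame) -> tuple[pd.Series, list[dict]]:
    """Eligibility per baby: term/near-term and completed (or died during) cooling.

    Returns a boolean Series indexed by infant_id and an exclusion log.
    Eligible iff gestational age >= 36 weeks and either cooled on 3 days or
    died while cooling was being given before 3 days were completed.
    """
    summ = _cooling_summary(days).reindex(infants["infant_id"]).fillna(0)
    ga = infants.set_index("infant_id")["gestational_age_weeks"]
    death_day = infants.set_index("infant_id")["death_day"]
    death_flag = infants.set_index("infant_id")["death_flag"] == 1

    cooled3 = summ["cooled_days"] >= 3
    # death on a cooled day before completing the third day of cooling
    cooled_on_death_day = pd.Series(False, index=ga.index)
    dd = death_day.dropna()
    if len(dd):
        keyed = days.set_index(["infant_id", "day"])["cooled"]
        idx = pd.MultiIndex.from_arrays([dd.index, dd.astype(int)])
        vals = keyed.reindex(idx).to_numpy()
        cooled_on_death_day.loc[dd.index] = vals == 1
    died_during = death_flag & (death_day <= 3) & cooled_on_death_day & ~cooled3

    exclusions: list[dict] = []
    ga_missing = ga.isna()
    eligible = ~ga_missing & (ga >= 36) & (cooled3 | died_during)
    for iid in ga.index[ga_missing]:
        exclusions.append({"infant_id": iid, "reason": "missing gestational age"})
    for iid in ga.index[~ga_missing & (ga < 36)]:
        exclusions.append({"infant_id": iid, "reason": "gestational age < 36 weeks"})
    for iid in ga.index[~ga_missing & (ga >= 36) & ~(cooled3 | died_during)]:
        exclusions.append({"infant_id": iid, "reason": "did not complete cooling nor die during it"})
    return eligible, exclusions


def classify_exposure(
    days: pd.DataFrame, eligible_ids, policy: str = "missing_as_unfed"
) -> tuple[pd.Series, list[dict]]:
    """FED / UNFED per eligible baby.

    FED iff enteral feeds are recorded on at least one day of the cooling
    period.  ``missing_as_unfed`` (default) counts a missing feeding cell as
    not fed; ``drop_missing`` instead excludes babies with any missing
    feeding data during the first 4 days.
    """
    if policy not in ("missing_as_unfed", "drop_missing"):
        raise ValueError(f"unknown exposure policy {policy!r}")
    eligible_ids = pd.Index(eligible_ids)
    sub = days[days["infant_id"].isin(eligible_ids)]
    fed_on_cooling = sub[(sub["cooled"] == 1) & (sub["enteral_fed"] == 1)]["infant_id"].unique()
    exposure = pd.Series("UNFED", index=eligible_ids, name="exposure")
    exposure.loc[exposure.index.intersection(fed_on_cooling)] = "FED"

    exclusions: list[dict] = []
    if policy == "drop_missing":
        # a baby with any missing enteral_fed cell on days 1-4 is dropped
        early = sub[sub["day"] <= 4]
        missing_any = early[early["enteral_fed"].isna()]["infant_id"].unique()
        drop = pd.Index(missing_any).intersection(eligible_ids)
        for iid in drop:
            exclusions.append({"infant_id": iid, "reason": "missing nutrition data in first 4 days"})
        exposure = exposure.drop(drop)
    return exposure, exclusions


def infants_with_qualifying_run(
    days: pd.DataFrame, flags: list[str], min_len: int, min_start: int | None = None
) -> pd.Index:
    """Babies having a run of >= min_len consecutive days with all flags true.

    A run is broken by a day on which any flag is false or missing, or by a
    gap in day numbering.  If min_start is given the run must commence on a
    day >= min_start.
    """
    d = days.sort_values(["infant_id", "day"], kind="mergesort")
    ok = np.ones(len(d), dtype=bool)
    for f in flags:
        ok &= (d[f] == 1).to_numpy()
    iid = d["infant_id"].to_numpy()
    day = d["day"].to_numpy()
    if len(d) == 0:
        return pd.Index([])
    cont = np.zeros(len(d), dtype=bool)
    cont[1:] = ok[1:] & ok[:-1] & (iid[1:] == iid[:-1]) & (day[1:] == day[:-1] + 1)
    start = ok & ~cont
    run_id = np.cumsum(start)
    run_id[~ok] = 0
    lengths = np.bincount(run_id)[1:]  # run ids 1..K
    start_days = day[start]
    start_infants = iid[start]
    qual = lengths >= min_len
    if min_start is not None:
        qual &= start_days >= min_start
    return pd.Index(pd.unique(start_infants[qual]))


def pragmatic_late_onset_infection(days: pd.DataFrame, infant_ids) -> pd.Series:
    """>=5 consecutive antibiotic days with the run commencing after day 3."""
    hit = infants_with_qualifying_run(days, ["antibiotics"], min_len=5, min_start=4)
    idx = pd.Index(infant_ids)
    return pd.Series(idx.isin(hit), index=idx, name="pragmatic_late_onset_infection")


def pragmatic_nec(infants: pd.DataFrame, days: pd.DataFrame, infant_ids) -> pd.Series:
    """Recorded NEC diagnosis plus >=5 consecutive days antibiotics while nil by mouth."""
    run = infants_with_qualifying_run(days, ["antibiotics", "nil_by_mouth"], min_len=5)
    idx = pd.Index(infant_ids)
    dx = infants.set_index("infant_id")["nec_diagnosis_recorded"].reindex(idx) == 1
    return pd.Series(idx.isin(run) & dx.to_numpy(), index=idx, name="pragmatic_nec")


def parse_blood_cultures(text: str) -> list[tuple[int, bool]]:
    """Decode 'day:flag;day:flag' culture strings."""
    if not isinstance(text, str) or not text.strip():
        return []
    out = []
    for item in text.split(";"):
        day, flag = item.split(":")
        out.append((int(day), flag.strip() == "1"))
    return out


def culture_positive_late_onset(infants: pd.DataFrame, infant_ids) -> pd.Series:
    """Pure growth of a pathogen from blood on day >= 4."""
    sub = infants.set_index("infant_id")["blood_cultures"].reindex(pd.Index(infant_ids))
    vals = [any(day >= 4 and pos for day, pos in parse_blood_cultures(t)) for t in sub]
    return pd.Series(vals, index=sub.index, name="culture_positive_late_onset")


def derive_secondary_outcomes(
    infants: pd.DataFrame, days: pd.DataFrame, infant_ids, growth_ref: GrowthReference | None = None
) -> pd.DataFrame:
    """Survival, length of stay, feeding milestones, line/PN durations, weight z."""
    if growth_ref is None:
        growth_ref = synthetic_reference()
    idx = pd.Index(infant_ids)
    inf = infants.set_index("infant_id").reindex(idx)
    sub = days[days["infant_id"].isin(idx)]

    out = pd.DataFrame(index=idx)
    death = inf["death_flag"] == 1
    out["survival_to_discharge"] = (~death).astype(float)
    out["length_of_stay"] = np.where(death, inf["death_day"], inf["discharge_day"])
    out["hypoglycaemia"] = (inf["hypoglycaemia_recorded"] == 1).astype(float)
    out["breastfeeding_at_discharge"] = inf["breastfeeding_at_discharge"]

    bf_days = sub[sub["breastfed_at_breast"] == 1].groupby("infant_id")["day"].min()
    out["onset_of_breastfeeding"] = bf_days.reindex(idx)
    mm = sub[sub["milk_type"] == "maternal"].groupby("infant_id")["day"].min()
    out["first_maternal_milk_day"] = mm.reindex(idx)
    out["parenteral_nutrition_days"] = (
        sub[sub["parenteral_nutrition"] == 1].groupby("infant_id")["day"].size().reindex(idx).fillna(0)
    )
    out["central_line_days"] = (
        sub[sub["central_line"] == 1].groupby("infant_id")["day"].size().reindex(idx).fillna(0)
    )
    pma = inf["gestational_age_weeks"] + (out["length_of_stay"] - 1) / 7.0
    out["weight_sd_score"] = growth_ref.sd_score(inf["discharge_weight_g"], pma, inf["sex"])
    return out


def year_band(years: pd.Series) -> pd.Series:
    bad = ~years.isin(YEAR_BANDS)
    if bad.any():
        raise ValueError(f"birth year outside 2010-2017: {sorted(years[bad].unique())}")
    return years.map(YEAR_BANDS)


def ph_band(ph: pd.Series) -> pd.Series:
    out = pd.Series("missing", index=ph.index, dtype=object)
    out[ph < 6.9] = "lt6.9"
    out[(ph >= 6.9) & (ph <= 7.0)] = "6.9to7.0"
    out[ph > 7.0] = "gt7.0"
    return out


def _expand_covariates(
    inf: pd.DataFrame, registry: tuple[Covariate, ...]
) -> tuple[pd.DataFrame, list[str], dict[str, str]]:
    cols = {}
    kinds: dict[str, str] = {}
    for cov in registry:
        x = inf[cov.name]
        n_missing = int(x.isna().sum())
        if cov.kind == "continuous":
            filled = x.fillna(x.mean())
            cols[cov.name] = filled.astype(float)
            kinds[cov.name] = "continuous"
        elif cov.kind == "binary":
            cols[cov.name] = x.fillna(0.0).astype(float)  # reference category
            kinds[cov.name] = "binary"
        else:  # categorical: reference level absorbed; missing -> reference
            for level in cov.levels[1:]:
                name = f"{cov.name}__{level}"
                cols[name] = (x == level).astype(float)
                kinds[name] = "binary"
        if n_missing > 0:
            name = f"{cov.name}__missing"
            cols[name] = x.isna().astype(float)
            kinds[name] = "binary"
    mat = pd.DataFrame(cols, index=inf.index)
    return mat, list(mat.columns), kinds


def build_analysis_table(
    infants: pd.DataFrame,
    days: pd.DataFrame,
    registry: tuple[Covariate, ...] = DEFAULT_REGISTRY,
    growth_ref: GrowthReference | None = None,
    exposure_policy: str = "missing_as_unfed",
    add_pn_day1_covariate: bool = False,
    restrict_years_from: int | None = None,
) -> AnalysisTable:
    """Full derivation: one analysis row per eligible baby."""
    if infants["infant_id"].duplicated().any():
        dup = infants.loc[infants["infant_id"].duplicated(), "infant_id"].iloc[0]
        raise ValueError(f"duplicate infant_id {dup!r}")

    days = impute_day2_cooling(days, infants)
    eligible, exclusions = assess_eligibility(infants, days)
    if restrict_years_from is not None:
        year = infants.set_index("infant_id")["birth_year"]
        late_enough = year >= restrict_years_from
        for iid in eligible.index[eligible & ~late_enough]:
            exclusions.append({"infant_id": iid, "reason": f"born before {restrict_years_from}"})
        eligible = eligible & late_enough
    eligible_ids = eligible.index[eligible]

    exposure, expo_excl = classify_exposure(days, eligible_ids, policy=exposure_policy)
    exclusions.extend(expo_excl)
    ids = exposure.index

    inf = infants.set_index("infant_id").reindex(ids)
    outcomes = pd.DataFrame(index=ids)
    outcomes["pragmatic_nec"] = pragmatic_nec(infants, days, ids).astype(float)
    outcomes["culture_positive_late_onset"] = culture_positive_late_onset(infants, ids).astype(float)
    outcomes["pragmatic_late_onset_infection"] = pragmatic_late_onset_infection(days, ids).astype(float)
    outcomes = outcomes.join(derive_secondary_outcomes(infants, days, ids, growth_ref))
    outcomes = outcomes[list(OUTCOME_COLUMNS)]

    reg = registry + ((PN_DAY1_COVARIATE,) if add_pn_day1_covariate else ())
    mat, cov_cols, kinds = _expand_covariates(inf, reg)

    df = pd.DataFrame({"infant_id": ids, "exposure": exposure.to_numpy()})
    df["year_band"] = year_band(inf["birth_year"]).to_numpy()
    df["ph_band"] = ph_band(inf["cord_arterial_ph"]).to_numpy()
    df = pd.concat(
        [df.set_index("infant_id"), mat, outcomes.add_prefix("out__")], axis=1
    ).reset_index(names="infant_id")
    return AnalysisTable(df=df, covariate_columns=cov_cols, column_kinds=kinds, exclusions=exclusions)
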