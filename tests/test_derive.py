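import numpy as np
import pandas as pd
import pytest

import oracles
from conftest import make_day_rows, make_infant, make_infants
from coolmatch.derive import (
    assess_eligibility,
    build_analysis_table,
    classify_exposure,
    culture_positive_late_onset,
    derive_secondary_outcomes,
    impute_day2_cooling,
    infants_with_qualifying_run,
    ph_band,
    pragmatic_late_onset_infection,
    pragmatic_nec,
    year_band,
)
from coolmatch.growth import synthetic_reference


def days_with_cooling(infant_id="B1", cooled=(1.0, 1.0, 1.0), n_days=12, **extra):
    cols = dict(extra)
    cols["cooled"] = list(cooled) + [0.0] * (n_days - len(cooled))
    for key in ("enteral_fed", "antibiotics", "nil_by_mouth"):
        if key in cols:
            cols[key] = list(cols[key]) + [0.0] * (n_days - len(cols[key]))
    return make_day_rows(infant_id, **cols)


class TestDay2Imputation:
    @pytest.mark.parametrize(
        "cooled, expected",
        [
            ((1.0, np.nan, 1.0), (1.0, 1.0, 1.0)),  # the imputable pattern
            ((1.0, np.nan, np.nan), (1.0, np.nan, np.nan)),
            ((np.nan, np.nan, 1.0), (np.nan, np.nan, 1.0)),
        ],
    )
    def test_patterns(self, cooled, expected):
        days = days_with_cooling(cooled=cooled, n_days=3)
        out = impute_day2_cooling(days)
        got = tuple(out.sort_values("day")["cooled"])
        assert got == pytest.approx(expected, nan_ok=True)

    def test_death_during_cooling_blocks_imputation(self):
        days = days_with_cooling(cooled=(1.0, np.nan, 1.0), n_days=3)
        infants = make_infants([make_infant(death_flag=1.0, death_day=3.0, discharge_day=3.0)])
        out = impute_day2_cooling(days, infants)
        assert np.isnan(out.sort_values("day")["cooled"].iloc[1])

    def test_no_other_cell_altered(self):
        days = days_with_cooling(cooled=(1.0, np.nan, 1.0), antibiotics=(np.nan, 1.0, 0.0), n_days=3)
        out = impute_day2_cooling(days)
        pd.testing.assert_series_equal(out["antibiotics"], days["antibiotics"])


class TestEligibility:
    def test_boundary_gestation_completed_cooling(self):
        infants = make_infants([make_infant(gestational_age_weeks=36.0)])
        eligible, _ = assess_eligibility(infants, days_with_cooling())
        assert eligible.loc["B1"]

    def test_below_threshold_ineligible(self):
        infants = make_infants([make_infant(gestational_age_weeks=35.9)])
        eligible, excl = assess_eligibility(infants, days_with_cooling())
        assert not eligible.loc["B1"]
        assert any("gestational age" in e["reason"] for e in excl)

    def test_death_during_cooling_is_eligible(self):
        infants = make_infants(
            [make_infant(gestational_age_weeks=40.0, death_flag=1.0, death_day=2.0, discharge_day=2.0)]
        )
        days = make_day_rows("B1", cooled=[1.0, 1.0])
        eligible, _ = assess_eligibility(infants, days)
        assert eligible.loc["B1"]

    def test_incomplete_cooling_survivor_ineligible(self):
        infants = make_infants([make_infant()])
        days = make_day_rows("B1", cooled=[1.0, 1.0] + [0.0] * 6)
        eligible, excl = assess_eligibility(infants, days)
        assert not eligible.loc["B1"]
        assert any("cooling" in e["reason"] for e in excl)

    def test_missing_gestation_logged(self):
        infants = make_infants([make_infant(gestational_age_weeks=np.nan)])
        eligible, excl = assess_eligibility(infants, days_with_cooling())
        assert not eligible.loc["B1"]
        assert excl[0]["reason"] == "missing gestational age"


class TestExposure:
    def test_fed_on_any_cooling_day(self):
        days = days_with_cooling(enteral_fed=(0.0, 1.0, 0.0))
        expo, _ = classify_exposure(days, ["B1"])
        assert expo.loc["B1"] == "FED"

    def test_feeding_after_cooling_is_unfed(self):
        days = days_with_cooling(enteral_fed=(0.0, 0.0, 0.0, 1.0))
        expo, _ = classify_exposure(days, ["B1"])
        assert expo.loc["B1"] == "UNFED"

    def test_all_missing_defaults_to_unfed(self):
        days = days_with_cooling(enteral_fed=(np.nan, np.nan, np.nan))
        expo, _ = classify_exposure(days, ["B1"])
        assert expo.loc["B1"] == "UNFED"

    def test_drop_missing_policy_excludes_instead(self):
        days = days_with_cooling(enteral_fed=(np.nan, np.nan, np.nan))
        expo, excl = classify_exposure(days, ["B1"], policy="drop_missing")
        assert "B1" not in expo.index
        assert excl[0]["reason"] == "missing nutrition data in first 4 days"

    def test_unknown_policy_rejected(self):
        with pytest.raises(ValueError):
            classify_exposure(days_with_cooling(), ["B1"], policy="bogus")


class TestPragmaticOutcomes:
    def test_nec_requires_diagnosis_and_run(self):
        run = [0.0] * 5 + [1.0] * 5  # days 6-10
        days = days_with_cooling(antibiotics=run, nil_by_mouth=run)
        with_dx = make_infants([make_infant(nec_diagnosis_recorded=1.0)])
        without_dx = make_infants([make_infant(nec_diagnosis_recorded=0.0)])
        assert pragmatic_nec(with_dx, days, ["B1"]).loc["B1"]
        assert not pragmatic_nec(without_dx, days, ["B1"]).loc["B1"]

    def test_nec_overlap_must_reach_five_days(self):
        abx = [0.0] * 5 + [1.0] * 5  # days 6-10
        nbm = [0.0] * 5 + [1.0] * 4 + [0.0]  # days 6-9 only
        days = days_with_cooling(antibiotics=abx, nil_by_mouth=nbm)
        infants = make_infants([make_infant(nec_diagnosis_recorded=1.0)])
        assert not pragmatic_nec(infants, days, ["B1"]).loc["B1"]

    @pytest.mark.parametrize(
        "abx_days, expected",
        [
            (range(4, 9), True),  # run commences day 4
            (range(2, 10), False),  # run commences day 2
            (range(5, 9), False),  # only 4 days
        ],
    )
    def test_late_onset_infection_run_start_rule(self, abx_days, expected):
        abx = [1.0 if d in set(abx_days) else 0.0 for d in range(1, 13)]
        days = days_with_cooling(antibiotics=abx)
        assert pragmatic_late_onset_infection(days, ["B1"]).loc["B1"] is np.True_ if expected else not pragmatic_late_onset_infection(days, ["B1"]).loc["B1"]

    def test_missing_day_breaks_run(self):
        # antibiotics on days 4,5,6,8,9: the gap at day 7 splits the run
        days = make_day_rows("B1", day=[4, 5, 6, 8, 9], antibiotics=[1.0] * 5, cooled=[0.0] * 5)
        assert not pragmatic_late_onset_infection(days, ["B1"]).loc["B1"]

    def test_runs_match_brute_force_enumeration(self):
        rng = np.random.default_rng(99)
        frames, truth_loi, truth_nec_run = [], {}, {}
        for i in range(1000):
            iid = f"R{i}"
            rows = oracles.random_day_table(rng)
            frames.append(
                make_day_rows(
                    iid,
                    day=[r[0] for r in rows],
                    antibiotics=[r[1] for r in rows],
                    nil_by_mouth=[r[2] for r in rows],
                    cooled=[0.0] * len(rows),
                )
            )
            abx_map = {r[0]: r[1] == 1.0 for r in rows}
            both_map = {r[0]: (r[1] == 1.0 and r[2] == 1.0) for r in rows}
            truth_loi[iid] = oracles.brute_force_has_run(abx_map, 5, min_start=4)
            truth_nec_run[iid] = oracles.brute_force_has_run(both_map, 5)
        days = pd.concat(frames, ignore_index=True)
        ids = list(truth_loi)
        got_loi = pragmatic_late_onset_infection(days, ids)
        got_nec = infants_with_qualifying_run(days, ["antibiotics", "nil_by_mouth"], 5)
        for iid in ids:
            assert got_loi.loc[iid] == truth_loi[iid], iid
            assert (iid in got_nec) == truth_nec_run[iid], iid


class TestCulturesAndSecondary:
    def test_late_culture_day_rule(self):
        infants = make_infants(
            [
                make_infant("B1", blood_cultures="5:1"),
                make_infant("B2", blood_cultures="2:1"),
                make_infant("B3", blood_cultures=""),
                make_infant("B4", blood_cultures="2:1;7:0"),
            ]
        )
        got = culture_positive_late_onset(infants, ["B1", "B2", "B3", "B4"])
        assert got.tolist() == [True, False, False, False]

    def test_death_gives_survival_false_and_los(self):
        infants = make_infants([make_infant(death_flag=1.0, death_day=2.0, discharge_day=2.0)])
        out = derive_secondary_outcomes(infants, make_day_rows("B1", cooled=[1.0, 1.0]), ["B1"])
        assert out.loc["B1", "survival_to_discharge"] == 0.0
        assert out.loc["B1", "length_of_stay"] == 2.0

    def test_breastfeeding_onset_first_day_at_breast(self):
        bfd = [0.0] * 6 + [1.0] * 4
        days = make_day_rows("B1", breastfed_at_breast=bfd, cooled=[1.0] * 3 + [0.0] * 7)
        infants = make_infants([make_infant()])
        out = derive_secondary_outcomes(infants, days, ["B1"])
        assert out.loc["B1", "onset_of_breastfeeding"] == 7

    def test_weight_at_reference_mean_scores_zero(self):
        ref = synthetic_reference()
        ga, los = 39.0, 12.0
        w = ref.mean_g([ga + (los - 1) / 7.0], ["female"])[0]
        infants = make_infants([make_infant(discharge_weight_g=w, discharge_day=los)])
        out = derive_secondary_outcomes(infants, days_with_cooling(), ["B1"], ref)
        assert out.loc["B1", "weight_sd_score"] == pytest.approx(0.0, abs=1e-12)

    def test_pn_and_line_days_are_counts(self):
        days = make_day_rows(
            "B1", parenteral_nutrition=[1.0, 1.0, 0.0, 1.0], central_line=[1.0] * 3 + [0.0], cooled=[1.0] * 3 + [0.0]
        )
        infants = make_infants([make_infant()])
        out = derive_secondary_outcomes(infants, days, ["B1"])
        assert out.loc["B1", "parenteral_nutrition_days"] == 3
        assert out.loc["B1", "central_line_days"] == 3


class TestBandsAndTable:
    @pytest.mark.parametrize(
        "ph, band", [(6.85, "lt6.9"), (6.9, "6.9to7.0"), (7.0, "6.9to7.0"), (7.05, "gt7.0"), (np.nan, "missing")]
    )
    def test_ph_bands(self, ph, band):
        assert ph_band(pd.Series([ph])).iloc[0] == band

    @pytest.mark.parametrize("year, band", [(2010, "2010-11"), (2013, "2012-13"), (2015, "2014-15"), (2017, "2016-17")])
    def test_year_bands(self, year, band):
        assert year_band(pd.Series([year])).iloc[0] == band

    def test_year_outside_range_rejected(self):
        with pytest.raises(ValueError):
            year_band(pd.Series([2009]))

    def test_duplicate_infant_rejected(self):
        infants = make_infants([make_infant(), make_infant()])
        with pytest.raises(ValueError, match="duplicate"):
            build_analysis_table(infants, days_with_cooling())

    def test_missing_covariate_gets_indicator_and_mean(self, small_cohort):
        _, infants, days, _ = small_cohort
        at = build_analysis_table(infants, days)
        assert "cord_arterial_ph__missing" in at.covariate_columns
        ph = at.df["cord_arterial_ph"]
        assert not ph.isna().any()
        raw = infants.set_index("infant_id")["cord_arterial_ph"].reindex(at.df["infant_id"])
        observed_mean = raw.mean()
        imputed = at.df.loc[raw.isna().to_numpy(), "cord_arterial_ph"]
        assert np.allclose(imputed, observed_mean)

    def test_every_eligible_baby_has_exposure_and_outcomes(self, small_analysis):
        df = small_analysis.df
        assert df["exposure"].isin(["FED", "UNFED"]).all()
        out_cols = [c for c in df.columns if c.startswith("out__")]
        assert len(out_cols) == 12

    def test_order_independence(self, small_cohort):
        _, infants, days, _ = small_cohort
        shuffled = days.sample(frac=1.0, random_state=5).reset_index(drop=True)
        a = build_analysis_table(infants, days)
        b = build_analysis_table(infants, shuffled)
        pd.testing.assert_frame_equal(a.df, b.df)
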