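import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from coolmatch.matching import (
    assign_strata,
    balance_report,
    decile_bins,
    match_replicate,
    replicate_matching,
    standardized_difference,
)
from coolmatch.matching import ReplicateSet, child_seed


def make_table(n_fed, n_unfed, strata_labels=None, scores=None, rng=None):
    n = n_fed + n_unfed
    rng = rng or np.random.default_rng(0)
    df = pd.DataFrame(
        {
            "infant_id": [f"I{i}" for i in range(n)],
            "exposure": ["FED"] * n_fed + ["UNFED"] * n_unfed,
            "score": scores if scores is not None else rng.random(n),
        }
    )
    strata = pd.Series(strata_labels if strata_labels is not None else ["s"] * n, index=df.index)
    return df, strata


class TestStrata:
    def test_band_assignment(self):
        df = pd.DataFrame({"year_band": ["2010-11", "2016-17"], "ph_band": ["gt7.0", "missing"]})
        keys = assign_strata(df)
        assert keys.tolist() == ["2010-11|gt7.0", "2016-17|missing"]

    def test_sixteen_possible_cells(self):
        years = ["2010-11", "2012-13", "2014-15", "2016-17"]
        phs = ["lt6.9", "6.9to7.0", "gt7.0", "missing"]
        df = pd.DataFrame(
            [(y, p) for y, p in itertools.product(years, phs)], columns=["year_band", "ph_band"]
        )
        assert assign_strata(df).nunique() == 16

    def test_strict_twelve_groups_drop_missing_ph(self):
        df = pd.DataFrame({"year_band": ["2010-11", "2012-13"], "ph_band": ["missing", "gt7.0"]})
        keys = assign_strata(df, drop_missing_ph=True)
        assert keys.isna().tolist() == [True, False]


class TestDecileBins:
    def test_ten_distinct_scores_one_per_bin(self):
        labels = decile_bins(np.arange(10) / 10.0)
        assert sorted(labels) == list(range(1, 11))

    def test_all_equal_scores_single_bin(self):
        labels = decile_bins(np.full(25, 0.4))
        assert set(labels) == {1}

    def test_hundred_uniform_scores_ten_per_bin(self):
        rng = np.random.default_rng(3)
        scores = rng.random(100)
        labels = decile_bins(scores)
        assert np.bincount(labels)[1:].tolist() == [10] * 10
        assert np.array_equal(labels, oracles.sort_split_deciles(scores))

    def test_boundary_score_goes_to_lower_bin(self):
        scores = np.arange(1, 11, dtype=float)  # deciles at 1.9, 2.8, ..., 9.1
        labels = decile_bins(scores)
        edges = np.quantile(scores, np.arange(1, 10) / 10)
        # a score exactly equal to an edge must take the lower label
        probe = decile_bins(np.concatenate([scores, [edges[0]]]))
        assert probe[-1] == 1
        assert labels[0] == 1

    @pytest.mark.parametrize("seed", [0, 7, 19])
    def test_matches_sort_split_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.random(rng.integers(3, 60)), 2)  # ties likely
        assert np.array_equal(decile_bins(scores), oracles.sort_split_deciles(scores))

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0.001, 0.999), min_size=1, max_size=80))
    def test_sort_split_oracle_property(self, raw):
        scores = np.round(np.asarray(raw), 3)
        assert np.array_equal(decile_bins(scores), oracles.sort_split_deciles(scores))


class TestMatchReplicate:
    def test_single_pair_cell_deterministic(self):
        df, strata = make_table(1, 1)
        bins = pd.Series([1, 1])
        for seed in (0, 1, 99):
            pairs = match_replicate(df, strata, bins, seed)
            assert len(pairs) == 1
            assert pairs.loc[0, "fed_id"] == "I0" and pairs.loc[0, "unfed_id"] == "I1"

    def test_min_rule_leaves_surplus_unmatched(self):
        df, strata = make_table(3, 5)
        bins = pd.Series([1] * 8)
        pairs = match_replicate(df, strata, bins, 0)
        assert len(pairs) == 3
        assert pairs["fed_id"].is_unique and pairs["unfed_id"].is_unique

    @pytest.mark.parametrize("seed", [1, 2, 3, 4])
    def test_pair_count_equals_cell_census(self, seed):
        rng = np.random.default_rng(seed)
        n = 120
        exposure = np.where(rng.random(n) < 0.4, "FED", "UNFED")
        strata_lab = rng.choice(["a", "b", "c"], n)
        bins = pd.Series(rng.integers(1, 4, n))
        df = pd.DataFrame({"infant_id": [f"I{i}" for i in range(n)], "exposure": exposure, "score": rng.random(n)})
        pairs = match_replicate(df, pd.Series(strata_lab), bins, seed)
        fed_cells, unfed_cells = {}, {}
        for i in range(n):
            key = (strata_lab[i], int(bins[i]))
            d = fed_cells if exposure[i] == "FED" else unfed_cells
            d[key] = d.get(key, 0) + 1
        assert len(pairs) == oracles.census_pair_count(fed_cells, unfed_cells)
        # no baby appears twice within the replicate
        all_ids = pd.concat([pairs["fed_id"], pairs["unfed_id"]])
        assert all_ids.is_unique

    def test_pairs_share_stratum_and_decile(self):
        rng = np.random.default_rng(5)
        df, strata = make_table(30, 40, strata_labels=rng.choice(["x", "y"], 70).tolist(), rng=rng)
        bins = pd.Series(rng.integers(1, 3, 70))
        pairs = match_replicate(df, strata, bins, 11)
        lookup_s = dict(zip(df["infant_id"], strata))
        lookup_b = dict(zip(df["infant_id"], bins))
        for row in pairs.itertuples():
            assert lookup_s[row.fed_id] == lookup_s[row.unfed_id] == row.stratum
            assert lookup_b[row.fed_id] == lookup_b[row.unfed_id] == row.decile


class TestReplicateMatching:
    def test_single_replicate_reduces_to_match_replicate(self):
        df, strata = make_table(10, 15)
        bins = pd.Series(np.ones(25, dtype=int))
        rs = replicate_matching(df, strata, bins, R=1, master_seed=123)
        direct = match_replicate(df, strata, bins, child_seed(123, 0))
        pd.testing.assert_frame_equal(rs.replicates[0], direct)

    def test_same_master_seed_identical(self):
        df, strata = make_table(20, 30)
        bins = pd.Series(np.ones(50, dtype=int))
        a = replicate_matching(df, strata, bins, R=5, master_seed=9)
        b = replicate_matching(df, strata, bins, R=5, master_seed=9)
        for ra, rb in zip(a.replicates, b.replicates):
            pd.testing.assert_frame_equal(ra, rb)
        assert a.seeds == b.seeds

    def test_pair_count_constant_across_replicates(self):
        rng = np.random.default_rng(8)
        df, strata = make_table(40, 60, strata_labels=rng.choice(["a", "b"], 100).tolist(), rng=rng)
        bins = pd.Series(rng.integers(1, 5, 100))
        rs = replicate_matching(df, strata, bins, R=10, master_seed=3)
        counts = {len(r) for r in rs.replicates}
        assert len(counts) == 1

    def test_invalid_replication_count(self):
        df, strata = make_table(2, 2)
        with pytest.raises(ValueError):
            replicate_matching(df, strata, pd.Series([1, 1, 1, 1]), R=0)


class TestStandardizedDifference:
    def test_identical_groups_zero(self):
        assert standardized_difference([1, 0, 1], [1, 0, 1], "binary") == 0.0

    def test_binary_formula_value(self):
        x1 = [1] * 5 + [0] * 5  # p1 = 0.5
        x2 = [1] * 4 + [0] * 6  # p2 = 0.4
        assert standardized_difference(x1, x2, "binary") == pytest.approx(0.1 / np.sqrt(0.245), abs=1e-10)

    def test_continuous_equal_means_zero(self):
        assert standardized_difference([1.0, 3.0], [0.0, 4.0], "continuous") == 0.0

    def test_continuous_formula(self):
        rng = np.random.default_rng(4)
        x1, x2 = rng.normal(0, 1, 50), rng.normal(0.3, 1.4, 60)
        expected = (x1.mean() - x2.mean()) / np.sqrt((x1.var(ddof=1) + x2.var(ddof=1)) / 2)
        assert standardized_difference(x1, x2, "continuous") == pytest.approx(expected, abs=1e-12)

    def test_missing_excluded_pairwise(self):
        assert standardized_difference([1.0, np.nan, 1.0], [1.0, 1.0], "binary") == 0.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            standardized_difference([], [1.0], "continuous")


class TestBalanceReport:
    @staticmethod
    def _setup(rng):
        n = 200
        stratum_var = rng.integers(0, 2, n).astype(float)  # exactly matched variable
        confounded = rng.normal(stratum_var, 1.0)
        exposure = np.where(rng.random(n) < 0.35 + 0.3 * stratum_var, "FED", "UNFED")
        df = pd.DataFrame(
            {
                "infant_id": [f"I{i}" for i in range(n)],
                "exposure": exposure,
                "is_band": stratum_var,
                "severity": confounded,
                "score": rng.random(n),
            }
        )
        strata = pd.Series(np.where(stratum_var == 1, "band1", "band0"))
        bins = pd.Series(np.ones(n, dtype=int))
        return df, strata, bins

    def test_exactly_matched_variable_balances_to_zero(self):
        rng = np.random.default_rng(10)
        df, strata, bins = self._setup(rng)
        rs = replicate_matching(df, strata, bins, R=5, master_seed=1)
        rep = balance_report(df, ["is_band"], {"is_band": "binary"}, rs)
        assert rep.loc[0, "after_mean"] == 0.0 and rep.loc[0, "after_sd"] == 0.0

    def test_matching_improves_confounded_balance(self):
        rng = np.random.default_rng(11)
        df, strata, bins = self._setup(rng)
        rs = replicate_matching(df, strata, bins, R=10, master_seed=2)
        rep = balance_report(df, ["is_band", "severity"], {"is_band": "binary", "severity": "continuous"}, rs)
        assert rep["after_mean"].abs().max() < rep["before"].abs().max()

    def test_empty_replicate_set_rejected(self):
        rng = np.random.default_rng(12)
        df, strata, bins = self._setup(rng)
        with pytest.raises(ValueError):
            balance_report(df, ["is_band"], {"is_band": "binary"}, ReplicateSet([], [], 0))
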