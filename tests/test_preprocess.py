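import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from carioca import (
    RoadRecord,
    annual_ratio_series,
    crude_ratio,
    impute_closure_counts,
    interpolate_population,
    moving_average_population,
    score_traffic,
    score_tunnels,
)
from carioca.preprocess import TUNNEL_FIXTURE_BINS, rank_bins
from conftest import make_count_panel, make_population_panel


class TestClosureImputation:
    def test_no_closure_is_identity(self):
        series = {2008: 100.0, 2009: 120.0, 2010: 90.0}
        assert impute_closure_counts(series, {}) == series
        assert impute_closure_counts(series, {2010: 0}) == series

    def test_two_month_closure(self):
        # 800 + mean(1200, 1000) * 2/12 = 983.33
        series = {2008: 1200, 2009: 1000, 2010: 800}
        out = impute_closure_counts(series, {2010: 2})
        assert out[2010] == pytest.approx(800 + 1100 * 2 / 12)

    def test_cascade_uses_corrected_years(self):
        # the multi-year schedule: 2010 over 2 months from mean(2008, 2009);
        # 2011 fully closed, from mean(2008, 2009, corrected 2010);
        # 2012 over 6 months from mean(2008, 2009, corrected 2010, corrected 2011)
        series = {2008: 1200, 2009: 1000, 2010: 800, 2011: 0, 2012: 400}
        out = impute_closure_counts(series, {2010: 2, 2011: 12, 2012: 6})
        c10 = 800 + (1200 + 1000) / 2 * 2 / 12
        c11 = 0 + (1200 + 1000 + c10) / 3 * 12 / 12
        c12 = 400 + (1200 + 1000 + c10 + c11) / 4 * 6 / 12
        assert out[2010] == pytest.approx(c10)
        assert out[2011] == pytest.approx(c11)
        assert out[2012] == pytest.approx(c12)
        # frozen hand-computed values
        assert out[2010] == pytest.approx(983.333333, abs=1e-5)
        assert out[2011] == pytest.approx(1061.111111, abs=1e-5)
        assert out[2012] == pytest.approx(930.555556, abs=1e-5)

    def test_correction_only_increases_with_positive_history(self):
        series = {2008: 500, 2009: 700, 2010: 100}
        out = impute_closure_counts(series, {2010: 6})
        assert out[2010] > series[2010]

    def test_rejects_invalid_months(self):
        with pytest.raises(ValueError, match="0..12"):
            impute_closure_counts({2008: 1, 2009: 1, 2010: 1}, {2010: 13})

    def test_rejects_insufficient_history(self):
        with pytest.raises(ValueError, match="prior years"):
            impute_closure_counts({2009: 100, 2010: 50}, {2010: 3})


class TestPopulation:
    def test_census_shares_applied_to_city_totals(self):
        census = make_population_panel(["a", "b", "c"], [2010], [500, 300, 200])
        totals = pd.DataFrame(
            {"year": [2011, 2012], "stratum": "total", "population": [1000, 2000]}
        )
        out = interpolate_population(census, totals)
        p11 = out[out.year == 2011].set_index("area_id")["population"]
        assert p11["a"] == pytest.approx(500.0)
        assert p11["b"] == pytest.approx(300.0)
        assert p11["c"] == pytest.approx(200.0)

    def test_conserves_city_total_exactly(self):
        rng = np.random.default_rng(4)
        census = make_population_panel([f"a{i}" for i in range(7)], [2010],
                                       rng.uniform(1e4, 1e6, 7))
        totals = pd.DataFrame(
            {"year": [2013], "stratum": "total", "population": [6_000_000.0]}
        )
        out = interpolate_population(census, totals)
        assert out["population"].sum() == pytest.approx(6_000_000.0, abs=1e-6)

    def test_rejects_missing_year(self):
        census = make_population_panel(["a"], [2010], [100])
        totals = pd.DataFrame(
            {"year": [2011], "stratum": "male", "population": [10.0]}
        )
        with pytest.raises(ValueError, match="total"):
            interpolate_population(census, totals)

    def test_moving_average_of_three_prior_years(self):
        panel = make_population_panel(["a"], [2013, 2014, 2015], [1.0])
        panel["population"] = [90.0, 100.0, 110.0]
        out = moving_average_population(panel, [2016])
        val = out[(out.year == 2016)]["population"].iloc[0]
        assert val == pytest.approx(100.0)

    def test_recursion_uses_imputed_year(self):
        panel = make_population_panel(["a"], [2013, 2014, 2015], [1.0])
        panel["population"] = [90.0, 100.0, 110.0]
        out = moving_average_population(panel, [2016, 2017])
        v16 = 100.0
        v17 = (100.0 + 110.0 + v16) / 3
        got = out[(out.year == 2017)]["population"].iloc[0]
        assert got == pytest.approx(v17)

    def test_rejects_short_history(self):
        panel = make_population_panel(["a"], [2014, 2015], [10.0])
        with pytest.raises(ValueError, match="three years"):
            moving_average_population(panel, [2016])


class TestRatios:
    def test_definition_per_1000(self):
        counts = make_count_panel(["a"], [2013], {2013: [5]})
        pop = make_population_panel(["a"], [2013], [1000.0])
        assert crude_ratio(counts, pop, [2013])["a"] == pytest.approx(5.0)

    def test_zero_counts(self):
        counts = make_count_panel(["a"], [2013], {2013: [0]})
        pop = make_population_panel(["a"], [2013], [1000.0])
        assert crude_ratio(counts, pop, [2013])["a"] == 0.0

    def test_pooled_two_year_window(self):
        counts = make_count_panel(["a"], [2013, 2014], {2013: [10], 2014: [20]})
        pop = make_population_panel(["a"], [2013, 2014], [1000.0])
        assert crude_ratio(counts, pop, [2013, 2014])["a"] == pytest.approx(15.0)

    def test_rejects_uncovered_window(self):
        counts = make_count_panel(["a"], [2013], {2013: [1]})
        pop = make_population_panel(["a"], [2013], [100.0])
        with pytest.raises(ValueError, match="2014"):
            crude_ratio(counts, pop, [2013, 2014])

    @given(
        c1=st.integers(0, 500), c2=st.integers(0, 500),
        p1=st.floats(10, 1e5), p2=st.floats(10, 1e5),
    )
    @settings(max_examples=50, deadline=None)
    def test_window_split_pooling_invariance(self, c1, c2, p1, p2):
        counts = make_count_panel(["a"], [2013, 2014], {2013: [c1], 2014: [c2]})
        pop = make_population_panel(["a"], [2013], [p1])
        pop2 = make_population_panel(["a"], [2014], [p2])
        pop = pd.concat([pop, pop2], ignore_index=True)
        pooled = crude_ratio(counts, pop, [2013, 2014])["a"]
        assert pooled == pytest.approx((c1 + c2) / (p1 + p2) * 1000)

    def test_annual_series_hand_case(self):
        counts = make_count_panel(["a"], [2013, 2014], {2013: [2], 2014: [4]})
        pop = make_population_panel(["a"], [2013, 2014], [1000.0])
        series = annual_ratio_series(counts, pop, [2013, 2014])
        assert series.loc["a", 2013] == pytest.approx(2.0)
        assert series.loc["a", 2014] == pytest.approx(4.0)

    def test_epidemic_doubling_doubles_that_year_only(self):
        from carioca import simulate_panel_with_artifacts

        counts = make_count_panel(["a"], [2013, 2014], {2013: [50], 2014: [50]})
        pop = make_population_panel(["a"], [2013, 2014], [1000.0])
        spiked = simulate_panel_with_artifacts(counts, epidemic_year=2014)
        series = annual_ratio_series(spiked, pop, [2013, 2014])
        assert series.loc["a", 2014] == pytest.approx(
            2 * series.loc["a", 2013]
        )


class TestTrafficScoring:
    def test_multiple_monitors_average(self):
        assert RoadRecord("r1", "a", [100.0, 200.0]).density == pytest.approx(150.0)

    def test_quartile_weights_by_rank(self):
        roads = [
            RoadRecord(f"r{i}", f"a{i}", [d]) for i, d in enumerate([10, 20, 30, 40])
        ]
        scores, sums = score_traffic(roads)
        assert list(sums[[f"a{i}" for i in range(4)]]) == [1, 2, 3, 4]

    def test_road_without_data_contributes_zero(self):
        roads = [
            RoadRecord("r1", "a", [50.0]),
            RoadRecord("r2", "b", [60.0]),
            RoadRecord("r3", "a", []),
        ]
        _, sums = score_traffic(roads)
        assert sums["a"] < sums["b"] or sums["a"] == sums["b"] - 1

    def test_rejects_empty_and_negative(self):
        with pytest.raises(ValueError):
            score_traffic([])
        with pytest.raises(ValueError, match="negative"):
            RoadRecord("r", "a", [-1.0])

    @given(st.lists(st.floats(1, 1e4), min_size=5, max_size=20, unique=True))
    @settings(max_examples=50, deadline=None)
    def test_rank_bins_invariant_under_monotone_rescaling(self, values):
        v = np.array(values)
        assert np.array_equal(rank_bins(v, 4), rank_bins(np.log(v) * 3 + 7, 4))

    @given(st.permutations(list(range(8))))
    @settings(max_examples=30, deadline=None)
    def test_score_invariant_to_road_relabeling(self, perm):
        densities = [5.0, 11.0, 23.0, 31.0, 47.0, 59.0, 61.0, 73.0]
        roads = [RoadRecord(f"r{i}", f"a{i}", [densities[i]]) for i in range(8)]
        shuffled = [RoadRecord(f"r{i}", f"a{i}", [densities[i]]) for i in perm]
        s1, _ = score_traffic(roads)
        s2, _ = score_traffic(shuffled)
        pd.testing.assert_series_equal(s1, s2)


class TestTunnelScoring:
    def test_fixture_bins_match_published_categories(self):
        counts = {"x": 0, "y": 22, "z": 3, "w": 35, "v": 8}
        scores = score_tunnels(counts, bins=TUNNEL_FIXTURE_BINS)
        assert scores["x"] == 1  # "0"
        assert scores["z"] == 2  # "1-5"
        assert scores["v"] == 3  # "6-15"
        assert scores["y"] == 4  # "16-30"
        assert scores["w"] == 5  # ">30"

    def test_equal_counts_share_a_score(self):
        scores = score_tunnels({"a": 4, "b": 4, "c": 4})
        assert scores.nunique() == 1

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            score_tunnels({"a": -1})

    def test_quintiles_without_bins(self):
        scores = score_tunnels({f"a{i}": i for i in range(5)})
        assert sorted(scores) == [1, 2, 3, 4, 5]
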