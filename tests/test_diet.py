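"""Prey biomass, electivity, key prey, and crane-fly peak timing."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arcticmismatch.diet import (
    biomass_equivalents,
    cranefly_peak_timing,
    default_allometry,
    interpolate_daily_biomass,
    ivlev_index,
    ivlev_table,
    key_prey,
    length_to_biomass,
)


class TestAllometry:
    def test_identity_law(self):
        table = default_allometry()
        table.site["Testidae"] = (1.0, 1.0)
        assert length_to_biomass("Testidae", 5.0, table) == pytest.approx(5.0)

    def test_power_law_evaluation(self):
        table = default_allometry()
        table.site["Testidae"] = (0.005, 2.59)
        expected = 0.005 * 10**2.59  # ~1.947
        assert length_to_biomass("Testidae", 10.0, table) == pytest.approx(expected)
        assert expected == pytest.approx(1.947, abs=0.002)

    def test_zero_length(self):
        assert length_to_biomass("Tipulidae", 0.0) == 0.0

    def test_tier_fallback_order(self):
        table = default_allometry()
        assert table.lookup("Tipulidae")[2] == "site"
        assert table.lookup("Muscidae")[2] == "fallback_site"
        assert table.lookup("Sciaridae")[2] == "order"
        with pytest.raises(KeyError, match="Unknownidae"):
            table.lookup("Unknownidae")


def _one_interval(total_mg_at_length, station=0):
    # a single 5-day interval whose catch weighs 10 mg in total
    return pd.DataFrame(
        {
            "station": [station],
            "year": [2021],
            "snowfree_day": [170.0],
            "interval_end": [175.0],
            "interval_days": [5],
            "family": ["Testidae"],
            "count": [1],
            "mean_length_mm": [total_mg_at_length],
        }
    )


class TestInterpolation:
    @pytest.fixture()
    def table(self):
        t = default_allometry()
        t.site["Testidae"] = (1.0, 1.0)  # mass == length, so totals are explicit
        return t

    def test_single_interval_anchor_conserves_total(self, table):
        rec = _one_interval(10.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            daily = interpolate_daily_biomass(rec, table)
        # 10 mg over 5 days -> 2 mg/day; the anchored daily rate times the
        # interval length returns the interval total exactly
        assert np.allclose(daily["biomass"], 2.0)
        assert abs(daily["biomass"].iloc[0] * 5 - 10.0) < 1e-9

    def test_linear_midpoint_between_anchors(self, table):
        rec = pd.DataFrame(
            {
                "station": [0, 0],
                "year": 2021,
                "snowfree_day": 170.0,
                "interval_end": [13.0, 18.0],
                "interval_days": [5, 5],
                "family": "Testidae",
                "count": [1, 1],
                "mean_length_mm": [10.0, 20.0],  # 2 and 4 mg/day anchors
            }
        )
        daily = interpolate_daily_biomass(rec, table)
        day13 = daily.loc[daily["day"] == 13, "biomass"].iloc[0]
        assert day13 == pytest.approx(3.0)

    def test_daily_station_passthrough(self, table):
        rec = pd.DataFrame(
            {
                "station": 0,
                "year": 2021,
                "snowfree_day": 170.0,
                "interval_end": np.arange(171.0, 176.0),
                "interval_days": 1,
                "family": "Testidae",
                "count": 1,
                "mean_length_mm": [1.0, 2.0, 3.0, 2.0, 1.0],
            }
        )
        _, anchors = interpolate_daily_biomass(rec, table, return_anchors=True)
        assert np.allclose(anchors["daily_rate"], rec["mean_length_mm"])

    def test_interval_conservation_property(self, table):
        # anchoring step: daily rate x interval length == interval biomass
        rng = np.random.default_rng(3)
        totals = rng.uniform(0.5, 30.0, 8)
        rec = pd.DataFrame(
            {
                "station": 0,
                "year": 2021,
                "snowfree_day": 170.0,
                "interval_end": 175.0 + 5 * np.arange(8.0),
                "interval_days": 5,
                "family": "Testidae",
                "count": 1,
                "mean_length_mm": totals,
            }
        )
        _, anchors = interpolate_daily_biomass(rec, table, return_anchors=True)
        assert np.allclose(
            anchors["daily_rate"] * anchors["interval_days"], totals, atol=1e-9
        )

    def test_proportions_sum_to_one(self, pitfalls):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            daily = interpolate_daily_biomass(pitfalls)
        sums = daily.dropna(subset=["proportion"]).groupby("day")["proportion"].sum()
        assert np.allclose(sums, 1.0)


class TestIvlev:
    @pytest.mark.parametrize(
        "O,E,expected",
        [(0.5, 0.5, 0.0), (0.6, 0.2, 0.5), (0.5, 0.0, 1.0), (0.0, 0.5, -1.0)],
    )
    def test_hand_values(self, O, E, expected):
        assert ivlev_index(O, E) == pytest.approx(expected)

    def test_undefined_when_both_zero(self):
        assert np.isnan(ivlev_index(0.0, 0.0))

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            ivlev_index(1.2, 0.5)

    @settings(deadline=None, max_examples=200)
    @given(
        O=st.floats(0.0, 1.0, allow_nan=False),
        E=st.floats(0.0, 1.0, allow_nan=False),
    )
    def test_bounds_and_antisymmetry(self, O, E):
        if O == 0.0 and E == 0.0:
            return
        v = ivlev_index(O, E)
        assert -1.0 <= v <= 1.0
        assert ivlev_index(E, O) == pytest.approx(-v, abs=1e-12)
        if O == E:
            assert v == 0.0


class TestKeyPrey:
    def _feces(self, fractions, n=20):
        rows = []
        for i in range(n):
            rows.append({"brood_id": f"B{i}", "date": 200, **fractions})
        return pd.DataFrame(rows)

    def test_threshold_rule(self):
        feces = self._feces({"Big": 0.548, "Small": 0.005, "Mid": 0.02})
        out = key_prey(feces)
        assert list(out["family"]) == ["Big", "Mid"]
        assert out["mean_fraction"].iloc[0] == pytest.approx(0.548)

    def test_order_invariance(self):
        feces = self._feces({"A": 0.3, "B": 0.2, "C": 0.1})
        shuffled = feces.sample(frac=1.0, random_state=1)
        pd.testing.assert_frame_equal(key_prey(feces), key_prey(shuffled))

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            key_prey(pd.DataFrame(columns=["brood_id", "date"]))

    def test_generated_diet_has_seven_key_families(self, config):
        from arcticmismatch.simulate import gen_fecal_diet

        feces = gen_fecal_diet(config, 2021, n_samples=40)
        out = key_prey(feces)
        out = out[out["family"] != "other"]
        assert len(out) == 7
        assert out["family"].iloc[0] == "Tipulidae"


class TestPeakTiming:
    def test_generator_lag_recovered(self, config, pitfalls):
        res = cranefly_peak_timing(pitfalls)
        n = len(res["station_means"])
        se = res["grand_sd"] / np.sqrt(n)
        assert abs(res["grand_mean"] - 29.0) < 2 * se + 0.5
        assert res["t_test"] is not None

    def test_identical_years_null_ttest(self):
        rows = []
        for year in (2018, 2019):
            for s in range(6):
                for day in (20 + s, 25 + s, 30 + s, 35 + s):  # station spread
                    rows.append(
                        {
                            "station": s, "year": year, "snowfree_day": 100.0,
                            "interval_end": 100.0 + day + 2.5, "interval_days": 5,
                            "family": "Tipulidae", "count": 3,
                            "mean_length_mm": 14.0,
                        }
                    )
        res = cranefly_peak_timing(pd.DataFrame(rows))
        assert res["t_test"]["t"] == pytest.approx(0.0, abs=1e-9)
        assert res["t_test"]["p"] == pytest.approx(1.0)

    def test_all_catches_on_snowfree_day(self):
        rows = [
            {
                "station": s, "year": 2019, "snowfree_day": 100.0,
                "interval_end": 101.0, "interval_days": 1, "family": "Tipulidae",
                "count": 2, "mean_length_mm": 14.0,
            }
            for s in range(3)
        ]
        res = cranefly_peak_timing(pd.DataFrame(rows))
        assert res["grand_mean"] == pytest.approx(0.5)
        prof = res["binned_profile"]
        assert prof["count"].sum() == 6
        assert str(prof["days_after"].iloc[0]) == "[0.0, 5.0)"

    def test_zero_cranefly_station_excluded(self, pitfalls):
        res = cranefly_peak_timing(pitfalls)
        with_cf = pitfalls[pitfalls["family"] == "Tipulidae"]
        qualifying = with_cf.groupby(["year", "station"]).ngroups
        assert len(res["station_means"]) == qualifying


def test_biomass_equivalents_midges_per_cranefly():
    assert biomass_equivalents(6.56, 0.10) == 66


def test_ivlev_table_matches_availability(config, pitfalls):
    from arcticmismatch.simulate import gen_fecal_diet

    feces = gen_fecal_diet(config, 2021, n_samples=10)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        daily = interpolate_daily_biomass(pitfalls)
    out = ivlev_table(feces, daily, ["Tipulidae", "Chironomidae"])
    assert out["ivlev"].dropna().between(-1, 1).all()
    assert set(out["family"]) == {"Tipulidae", "Chironomidae"}
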