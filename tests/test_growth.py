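"""Growth curves, condition index, age estimation, winter PC1."""

import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest

from arcticmismatch.config import ScenarioConfig
from arcticmismatch.growth import (
    asymptote_from_juveniles,
    body_size_pc1,
    condition_index,
    condition_regression,
    estimate_age_from_p10,
    fit_growth_model,
    juvenile_size_trend,
    logistic_curve,
    percent_scale,
    relative_hatch_date,
    von_bertalanffy_curve,
)
from arcticmismatch.simulate import (
    gen_chick_cohort,
    gen_juvenile_biometrics,
    realized_snowmelt,
)


def _noiseless_records(form, A, k, T, n_chicks=12):
    ages = np.tile(np.arange(0, 22, 2), n_chicks)
    ids = np.repeat([f"c{i}" for i in range(n_chicks)], 11)
    curve = logistic_curve if form == "logistic" else von_bertalanffy_curve
    return pd.DataFrame({"chick_id": ids, "age": ages, "trait": curve(ages, A, k, T)})


class TestGrowthFit:
    @pytest.mark.parametrize(
        "form,A,k,T",
        [("logistic", 25.0, 0.25, 8.0), ("von_bertalanffy", 33.0, 0.06, -7.5)],
    )
    def test_noiseless_recovery(self, form, A, k, T):
        df = _noiseless_records(form, A, k, T).rename(columns={"trait": "tarsus"})
        fit = fit_growth_model(df, "tarsus", form, A_fixed=A)
        assert abs(fit.k - k) < 1e-6
        assert abs(fit.T - T) < 1e-6

    def test_logistic_inflection_identity(self):
        df = _noiseless_records("logistic", 25.0, 0.25, 8.0).rename(
            columns={"trait": "tarsus"}
        )
        fit = fit_growth_model(df, "tarsus", "logistic", A_fixed=25.0)
        assert fit.predict(fit.T) == pytest.approx(fit.A / 2.0)

    def test_structural_trait_requires_asymptote(self):
        df = _noiseless_records("logistic", 25, 0.25, 8).rename(
            columns={"trait": "tarsus"}
        )
        with pytest.raises(ValueError, match="asymptote"):
            fit_growth_model(df, "tarsus", "logistic")

    def test_mean_residual_near_zero(self, config):
        cfg = dataclasses.replace(
            config, seed=321, n_broods_per_year=60, condition_slope_per_rhd=0.0
        )
        df = gen_chick_cohort(cfg, 2021)
        fit = fit_growth_model(df, "tarsus", "logistic", A_fixed=31.0)
        pred = fit.predict(df["age"].to_numpy())
        resid = df["tarsus"].to_numpy() - pred
        assert abs(resid.mean()) / resid.std() < 0.1

    def test_sd_k_recovered_within_30pct(self, config):
        # estimator check: cohorts generated from the growth model itself
        ests = []
        for seed in range(20):
            cfg = dataclasses.replace(
                config, seed=700 + seed, n_broods_per_year=50,
                condition_slope_per_rhd=0.0,
            )
            df = gen_chick_cohort(cfg, 2021)
            fit = fit_growth_model(df, "tarsus", "logistic", A_fixed=31.0)
            ests.append(fit.sd_k)
        truth = config.growth_params["tarsus"].sd_k
        assert abs(np.mean(ests) - truth) / truth < 0.30


class TestConditionIndex:
    @pytest.fixture(scope="class")
    def fit(self):
        df = _noiseless_records("logistic", 25.0, 0.25, 8.0).rename(
            columns={"trait": "tarsus"}
        )
        return fit_growth_model(df, "tarsus", "logistic", A_fixed=25.0)

    def test_zero_when_obs_equals_pred_and_arithmetic(self, fit):
        records = pd.DataFrame(
            {
                "chick_id": ["a", "b"],
                "brood_id": ["A", "B"],
                "year": 2021,
                "capture_day": [200, 200],
                "age": [10.0, 10.0],
                "tarsus": [fit.predict(10.0), 1.05 * fit.predict(10.0)],
            }
        )
        out, audit = condition_index(fit, records)
        assert out["value"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert out["value"].iloc[1] == pytest.approx(0.05)

    def test_young_chicks_excluded_with_audit(self, fit):
        records = pd.DataFrame(
            {
                "chick_id": list("abc"),
                "brood_id": list("ABC"),
                "year": 2021,
                "capture_day": [200] * 3,
                "age": [1.0, 2.0, np.nan],
                "tarsus": [10.0, 12.0, 14.0],
            }
        )
        out, audit = condition_index(fit, records)
        assert audit == {"n_in": 3, "n_missing": 1, "n_excluded_age": 1, "n_kept": 1}
        assert list(out["chick_id"]) == ["b"]

    def test_unit_rescaling_invariance(self, fit):
        records = pd.DataFrame(
            {
                "chick_id": ["a"], "brood_id": ["A"], "year": 2021,
                "capture_day": [200], "age": [12.0], "tarsus": [21.0],
            }
        )
        out_mm, _ = condition_index(fit, records)
        # same trait measured in cm: rescale data and curve alike
        df_cm = _noiseless_records("logistic", 2.5, 0.25, 8.0).rename(
            columns={"trait": "tarsus"}
        )
        fit_cm = fit_growth_model(df_cm, "tarsus", "logistic", A_fixed=2.5)
        out_cm, _ = condition_index(fit_cm, records.assign(tarsus=2.1))
        assert out_mm["value"].iloc[0] == pytest.approx(out_cm["value"].iloc[0], abs=1e-9)


class TestRelativeHatchDate:
    @pytest.mark.parametrize(
        "hatch,melt,expected", [(193, 180, 13), (180, 180, 0), (179, 180, -1)]
    )
    def test_arithmetic(self, hatch, melt, expected):
        assert relative_hatch_date(hatch, melt) == expected

    def test_missing_snowmelt_errors(self):
        with pytest.raises(ValueError):
            relative_hatch_date(193, None)


class TestConditionRegression:
    def _condition_table(self, config, seed, slope, n_broods=80):
        cfg = dataclasses.replace(
            config, seed=seed, n_broods_per_year=n_broods,
            condition_slope_per_rhd=slope,
        )
        melt = realized_snowmelt(cfg)
        years = cfg.year_list[-2:]
        chicks = pd.concat(
            [gen_chick_cohort(cfg, y, snowmelt=melt) for y in years],
            ignore_index=True,
        )
        fit = fit_growth_model(chicks, "tarsus", "logistic", A_fixed=31.0)
        cond, _ = condition_index(fit, chicks)
        meta = chicks.drop_duplicates("chick_id").set_index("chick_id")
        cond["rhd"] = [
            relative_hatch_date(meta.loc[c, "hatch_day"], melt[int(meta.loc[c, "year"])])
            for c in cond["chick_id"]
        ]
        cond["temp3d"] = meta.reindex(cond["chick_id"])["temp3d"].to_numpy()
        return cond

    def test_rhd_slope_recovered(self, config):
        cond = self._condition_table(config, seed=501, slope=-0.0024)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cmp_ = condition_regression(cond)
        assert "rhd" in cmp_.averaged_coef
        slope, se = cmp_.averaged_coef["rhd"], cmp_.averaged_se["rhd"]
        assert abs(slope - (-0.0024)) < 2.5 * se

    def test_null_effect_selects_intercept_only(self, config):
        wins = 0
        n_rep = 25
        for seed in range(n_rep):
            cond = self._condition_table(config, seed=900 + seed, slope=0.0, n_broods=30)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cmp_ = condition_regression(cond)
            if cmp_.best.terms == frozenset():
                wins += 1
        assert wins / n_rep >= 0.8

    def test_too_few_observations(self):
        df = pd.DataFrame(
            {"value": [0.1], "rhd": [1.0], "temp3d": [5.0], "year": [2020],
             "chick_id": ["a"]}
        )
        with pytest.raises(ValueError):
            condition_regression(df)


class TestAgeEstimation:
    def test_exact_linear_calibration(self):
        calib = pd.DataFrame({"p10": np.arange(0, 30, 2.0)})
        calib["age"] = 2 + 0.5 * calib["p10"]
        query = pd.DataFrame(
            {"chick_id": ["a"], "brood_id": ["A"], "p10": [10.0]}
        )
        out = estimate_age_from_p10(calib, query)
        assert out["age"].iloc[0] == pytest.approx(7.0)
        assert not out["extrapolated"].iloc[0]

    def test_query_at_mean_gives_mean_age(self):
        rng = np.random.default_rng(5)
        calib = pd.DataFrame({"p10": rng.uniform(0, 30, 40)})
        calib["age"] = 2 + 0.5 * calib["p10"] + rng.normal(0, 1, 40)
        query = pd.DataFrame(
            {"chick_id": ["a"], "brood_id": ["A"], "p10": [calib["p10"].mean()]}
        )
        out = estimate_age_from_p10(calib, query)
        assert out["age"].iloc[0] == pytest.approx(calib["age"].mean())

    def test_brood_averaging(self):
        calib = pd.DataFrame({"p10": np.arange(0, 30, 2.0)})
        calib["age"] = 2 + 0.5 * calib["p10"]
        query = pd.DataFrame(
            {
                "chick_id": list("abc"),
                "brood_id": ["B"] * 3,
                "p10": [(5 - 2) / 0.5, (6 - 2) / 0.5, (7 - 2) / 0.5],
            }
        )
        out = estimate_age_from_p10(calib, query)
        assert np.allclose(out["age"], 6.0)

    def test_empty_calibration_errors(self):
        with pytest.raises(ValueError):
            estimate_age_from_p10(
                pd.DataFrame({"age": [], "p10": []}),
                pd.DataFrame({"chick_id": ["a"], "brood_id": ["A"], "p10": [1.0]}),
            )


class TestBodySizePc1:
    def test_rank_one_traits(self):
        base = np.linspace(10, 20, 30)
        df = pd.DataFrame({"bill": base, "tarsus": 2 * base, "wing": 3 * base + 1})
        pca = body_size_pc1(df)
        assert pca["variance_explained"] == pytest.approx(100.0)
        loads = np.array(list(pca["loadings"].values()))
        assert np.allclose(loads, loads[0])

    def test_negation_symmetry(self):
        rng = np.random.default_rng(7)
        base = rng.normal(size=(40, 1)) @ np.ones((1, 3)) + rng.normal(
            0, 0.1, (40, 3)
        )
        df = pd.DataFrame(base, columns=["bill", "tarsus", "wing"])
        neg = -df
        p1, p2 = body_size_pc1(df), body_size_pc1(neg)
        assert np.allclose(p1["scores"].to_numpy(), -p2["scores"].to_numpy())
        assert np.allclose(
            list(p1["loadings"].values()), list(p2["loadings"].values())
        )

    def test_positive_loading_convention_and_dropped_rows(self, config):
        juv = gen_juvenile_biometrics(config)
        juv.loc[juv.index[:5], "wing"] = np.nan
        pca = body_size_pc1(juv)
        assert pca["n_dropped"] == 5
        assert all(v > 0 for v in pca["loadings"].values())

    def test_juvenile_pc1_declines_over_years(self, config):
        juv = gen_juvenile_biometrics(config)
        res = juvenile_size_trend(juv)
        assert "year_c" in res["comparison"].averaged_coef
        assert res["comparison"].averaged_coef["year_c"] < 0
        for t in ("bill", "tarsus", "wing"):
            assert res["trait_trends"][t]["slope"] < 0


def test_asymptote_averages_sex_means():
    juv = pd.DataFrame({"sex": [0, 0, 0, 1], "tarsus": [30.0, 30.0, 30.0, 32.0]})
    assert asymptote_from_juveniles(juv, "tarsus") == pytest.approx(31.0)


def test_percent_scale():
    assert np.allclose(percent_scale([20.0, 10.0], 20.0), [100.0, 50.0])
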