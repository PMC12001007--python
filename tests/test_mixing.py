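"""Single-isotope mixing model: oracles, invariances, trend regressions."""

import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest

from arcticmismatch.mixing import (
    DISCRIMINATION,
    McmcSettings,
    diet_trend_juveniles,
    diet_vs_hatch_chicks,
    fit_mixing_model,
    fit_mixing_models,
    posterior_means_frame,
    two_source_solution,
)

FAST = McmcSettings(chains=4, iterations=4000, burnin=500)


def grid_posterior_mean_2(d15n, mu, sd, delta_mean, delta_sd, sigma_prior=0.25):
    """Dense-grid posterior mean of p1 for two sources (independent oracle)."""
    p1 = np.linspace(0.0, 1.0, 2001)[:, None]
    s = np.linspace(1e-4, 4.0, 600)[None, :]
    p2 = 1.0 - p1
    m = p1 * (mu[0] + delta_mean) + p2 * (mu[1] + delta_mean)
    v = p1**2 * (sd[0] ** 2 + delta_sd**2) + p2**2 * (sd[1] ** 2 + delta_sd**2) + s**2
    lp = -0.5 * np.log(2 * np.pi * v) - (d15n - m) ** 2 / (2 * v)
    lp = lp - s**2 / (2 * sigma_prior**2)
    w = np.exp(lp - lp.max())
    w /= w.sum()
    return float((w.sum(axis=1) * p1[:, 0]).sum())


def grid_posterior_mean_3(d15n, mu, sd, delta_mean, delta_sd, sigma_prior=0.25):
    """Dense-grid posterior means (p1, p2, p3) for three sources."""
    g = np.linspace(0.0, 1.0, 201)
    p1, p2 = np.meshgrid(g, g, indexing="ij")
    mask = p1 + p2 <= 1.0
    p1, p2 = p1[mask], p2[mask]
    p3 = 1.0 - p1 - p2
    s = np.linspace(1e-4, 4.0, 300)[None, :]
    m = (p1 * (mu[0] + delta_mean) + p2 * (mu[1] + delta_mean)
         + p3 * (mu[2] + delta_mean))[:, None]
    v = (p1**2 * (sd[0] ** 2 + delta_sd**2) + p2**2 * (sd[1] ** 2 + delta_sd**2)
         + p3**2 * (sd[2] ** 2 + delta_sd**2))[:, None] + s**2
    lp = -0.5 * np.log(2 * np.pi * v) - (d15n - m) ** 2 / (2 * v)
    lp = lp - s**2 / (2 * sigma_prior**2)
    w = np.exp(lp - lp.max())
    w /= w.sum()
    wm = w.sum(axis=1)
    return np.array([(wm * p).sum() for p in (p1, p2, p3)])


def _src(mus, sds, names=None):
    names = names or [f"S{i}" for i in range(len(mus))]
    return pd.DataFrame({"family": names, "d15n_mean": mus, "d15n_sd": sds})


class TestSampler:
    def test_single_source_is_degenerate_simplex(self):
        res = fit_mixing_model(
            3.0 + 3.53, _src([3.0], [0.3]), settings=FAST, seed=1, store_draws=True
        )
        assert np.allclose(res.draws, 1.0)
        assert res.mean["S0"] == 1.0

    def test_symmetric_midpoint(self):
        mu = [0.0, 8.0]
        d = 4.0 + 3.53
        res = fit_mixing_model(d, _src(mu, [0.3, 0.3]), seed=2)
        assert abs(res.mean["S0"] - 0.5) < 0.02

    def test_draws_on_simplex(self):
        res = fit_mixing_model(
            6.0, _src([2.0, 6.0, 8.0], [0.5, 0.5, 0.5]), settings=FAST, seed=3,
            store_draws=True,
        )
        sums = res.draws.sum(axis=-1)
        assert np.allclose(sums, 1.0, atol=1e-12)
        assert (res.draws >= 0).all()

    def test_location_invariance(self):
        settings = FAST
        r1 = fit_mixing_model(5.53, _src([0.0, 8.0], [0.3, 0.3]), settings=settings, seed=5)
        r2 = fit_mixing_model(
            105.53, _src([100.0, 108.0], [0.3, 0.3]), settings=settings, seed=5
        )
        # identical log-posterior as a function of the chain state => identical draws
        assert r1.mean["S0"] == pytest.approx(r2.mean["S0"], abs=1e-12)

    @pytest.mark.parametrize("d15n", [3.53, 4.53, 5.53, 7.53, 11.53])
    def test_grid_oracle_two_sources(self, d15n):
        mu, sd = [0.0, 8.0], [0.3, 0.3]
        dm, dsd = DISCRIMINATION["juvenile_covert"]
        res = fit_mixing_model(d15n, _src(mu, sd), seed=11)
        oracle = grid_posterior_mean_2(d15n, mu, sd, dm, dsd)
        assert abs(res.mean["S0"] - oracle) < 0.02

    def test_grid_oracle_three_sources(self):
        mu, sd = [2.0, 6.0, 8.5], [0.5, 0.6, 0.6]
        dm, dsd = DISCRIMINATION["juvenile_covert"]
        d15n = 5.0 + dm
        res = fit_mixing_model(d15n, _src(mu, sd), seed=13)
        oracle = grid_posterior_mean_3(d15n, mu, sd, dm, dsd)
        got = np.array([res.mean[f] for f in res.families])
        assert np.max(np.abs(got - oracle)) < 0.02

    @pytest.mark.parametrize("p_true", [0.05, 0.25, 0.5, 0.75, 0.95])
    def test_near_noiseless_matches_closed_form(self, p_true):
        mu = [0.0, 8.0]
        dm, _ = DISCRIMINATION["juvenile_covert"]
        d15n = p_true * mu[0] + (1 - p_true) * mu[1] + dm
        src = _src(mu, [0.01, 0.01])
        res = fit_mixing_model(d15n, src, seed=17)
        closed = two_source_solution(d15n, dm, mu[0], mu[1])
        assert closed == pytest.approx(p_true, abs=1e-12)
        assert abs(res.mean["S0"] - closed) < 0.03

    def test_unknown_tissue_errors(self):
        with pytest.raises(ValueError):
            fit_mixing_model(5.0, _src([0.0], [0.1]), tissue="claw")


class TestJuvenileTrend:
    @pytest.fixture(scope="class")
    def juvenile_diet(self, config, sources_frame):
        from arcticmismatch.config import ScenarioTruth
        from arcticmismatch.simulate import gen_juvenile_biometrics

        truth = ScenarioTruth(config=config)
        juv = gen_juvenile_biometrics(config, truth=truth)
        juv["p_true"] = juv["bird_id"].map(truth.diet_by_bird)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results = fit_mixing_models(juv, sources_frame, seed=2)
        return juv.merge(posterior_means_frame(results), on="bird_id")

    def test_year_trend_recovered_up_to_measured_shrinkage(self, juvenile_diet):
        import statsmodels.formula.api as smf

        df = juvenile_diet
        true_slope = smf.ols("I(100*p_true) ~ year", df).fit().params["year"]
        shrink = smf.ols("p_mean ~ p_true", df).fit().params["p_true"]
        fit = smf.ols("I(100*p_mean) ~ year", df).fit()
        assert fit.params["year"] < 0  # diet declines over years
        assert fit.pvalues["year"] < 0.01
        assert abs(fit.params["year"] - shrink * true_slope) < 2 * fit.bse["year"]

    def test_model_selection_keeps_year(self, juvenile_diet):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cmp_ = diet_trend_juveniles(juvenile_diet)
        assert any("year_c" in c.terms for c in cmp_.selected)
        assert cmp_.averaged_coef["year_c"] < 0

    def test_null_trend_drops_year_from_best_model(self, config):
        # selection behaviour, tested on exact proportions (no MCMC noise)
        rng = np.random.default_rng(0)
        wins = 0
        n_rep = 50
        for _ in range(n_rep):
            n = 300
            year = rng.integers(2003, 2022, n)
            df = pd.DataFrame(
                {
                    "p_mean": np.clip(rng.normal(0.5, 0.15, n), 0, 1),
                    "year": year,
                    "snowmelt_day": 170 + rng.normal(0, 5, len(np.unique(year)))[
                        np.searchsorted(np.unique(year), year)
                    ],
                    "sex": rng.integers(0, 2, n),
                }
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cmp_ = diet_trend_juveniles(df)
            if "year_c" not in cmp_.best.terms:
                wins += 1
        assert wins / n_rep >= 0.8

    def test_collinear_year_snowmelt_warns(self):
        rng = np.random.default_rng(1)
        n = 100
        year = rng.integers(2003, 2022, n)
        df = pd.DataFrame(
            {
                "p_mean": rng.uniform(0, 1, n),
                "year": year,
                "snowmelt_day": 170 - 0.9 * (year - 2003),  # exact function of year
                "sex": rng.integers(0, 2, n),
            }
        )
        with pytest.warns(UserWarning, match="collinear"):
            cmp_ = diet_trend_juveniles(df)
        for c in cmp_.candidates:
            assert not {"year_c", "snowmelt_c"} <= c.terms

    def test_too_few_years(self):
        df = pd.DataFrame(
            {"p_mean": [0.5, 0.4], "year": [2003, 2004],
             "snowmelt_day": [170, 169], "sex": [0, 1]}
        )
        with pytest.raises(ValueError):
            diet_trend_juveniles(df)


class TestChickDiet:
    @pytest.fixture(scope="class")
    def chick_diet(self, config, chicks, snowmelt, sources_frame):
        from arcticmismatch.config import ScenarioTruth
        from arcticmismatch.simulate import gen_chick_feathers

        truth = ScenarioTruth(config=config)
        cf = gen_chick_feathers(config, chicks, truth=truth, snowmelt=snowmelt)
        cf["p_true"] = cf["bird_id"].map(truth.diet_by_bird)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results = fit_mixing_models(cf, sources_frame, tissue="chick_body", seed=3)
        return cf.merge(posterior_means_frame(results), on="bird_id")

    def test_rhd_slope_recovered_up_to_measured_shrinkage(self, chick_diet):
        import statsmodels.formula.api as smf

        df = chick_diet
        realized = smf.ols("I(100*p_true) ~ rhd", df).fit().params["rhd"]
        shrink = smf.ols("p_mean ~ p_true", df).fit().params["p_true"]
        fit = smf.ols("I(100*p_mean) ~ rhd", df).fit()
        assert abs(fit.params["rhd"] - shrink * realized) < 2 * fit.bse["rhd"]

    def test_generator_slope_matches_configured_across_seeds(self, config):
        import statsmodels.formula.api as smf
        from arcticmismatch.config import ScenarioTruth
        from arcticmismatch.simulate import (
            gen_chick_cohort,
            gen_chick_feathers,
            realized_snowmelt,
        )

        slopes = []
        for seed in range(8):
            cfg = dataclasses.replace(config, seed=4000 + 13 * seed)
            melt = realized_snowmelt(cfg)
            truth = ScenarioTruth(config=cfg)
            ch = pd.concat(
                [gen_chick_cohort(cfg, y, snowmelt=melt) for y in cfg.year_list[-2:]],
                ignore_index=True,
            )
            cf = gen_chick_feathers(cfg, ch, truth=truth, snowmelt=melt)
            cf["p_true"] = cf["bird_id"].map(truth.diet_by_bird)
            slopes.append(smf.ols("I(100*p_true) ~ rhd", cf).fit().params["rhd"])
        se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes) - config.diet_rhd_slope_chicks) < 3 * se

    def test_comparison_runs_with_brood_grouping(self, chick_diet):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cmp_ = diet_vs_hatch_chicks(chick_diet)
        assert len(cmp_.candidates) == 4

    def test_constant_rhd_is_degenerate(self):
        df = pd.DataFrame(
            {
                "p_mean": np.linspace(0.2, 0.8, 12),
                "rhd": 5.0,
                "year": [2018] * 6 + [2019] * 6,
                "brood_id": list("AABBCCDDEEFF"),
            }
        )
        with pytest.raises(ValueError, match="slope"):
            diet_vs_hatch_chicks(df)

    def test_single_brood_falls_back_with_warning(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {
                "p_mean": rng.uniform(0.2, 0.8, 12),
                "rhd": rng.normal(25, 5, 12),
                "year": 2019,
                "brood_id": "A",
            }
        )
        with pytest.warns(UserWarning, match="single brood"):
            diet_vs_hatch_chicks(df)
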