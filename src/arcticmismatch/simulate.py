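"""Synthetic study generator.

Produces the seven tables the analysis chain consumes — satellite snow-index
(NDSI) observations, a local snow-cover survey, longitudinal chick
biometrics, pitfall-trap catches, fecal diet fractions, prey isotope sources,
and winter juvenile biometrics with feather d15N — together with a
:class:`~arcticmismatch.config.ScenarioTruth` record of every realized
generating quantity, so each downstream estimator has a parameter-recovery
target.

Seasonal snow is generated from the same asymmetric-Gaussian family the
phenology module fits: the bare-ground fraction rises along a Gaussian spring
limb, peaks in mid-summer and declines along a wider autumn limb, with the
50% crossing of the snow fraction at the year's true snowmelt day.  Winter
body size is generated directly from the three-equation path model, so the
structural-equation module can be checked against known coefficients.
"""

from __future__ import annotations

from typing import Dict, Iterable, Optional, Tuple

import numpy as np
import pandas as pd

from .config import (
    ScenarioConfig,
    ScenarioTruth,
    rng_for_table,
)

__all__ = [
    "realized_snowmelt",
    "snow_probability",
    "gen_ndsi_year",
    "gen_local_survey",
    "gen_chick_cohort",
    "gen_pitfall_season",
    "gen_fecal_diet",
    "gen_isotope_data",
    "gen_chick_feathers",
    "gen_juvenile_biometrics",
    "generate_scenario",
    "write_scenario",
]

SEASON_DAYS = (60, 270)  # March-September day-of-year window
_HALF_WIDTH = np.sqrt(2.0 * np.log(2.0))  # half-maximum offset of a Gaussian limb

# Families other than crane flies share the rest of the diet; weights set the
# Dirichlet split of the non-crane-fly mass.
_OTHER_FAMILY_WEIGHTS = {
    "Chironomidae": 0.201,
    "Muscidae": 0.0486,
    "Carabidae": 0.0486,
    "Linyphiidae": 0.0486,
    "Mycetophilidae": 0.0486,
    "Ichneumonidae": 0.0486,
}

# Pitfall catch morphology: (mean length mm, length SD, expected total catch
# per station per season, emergence lag after station snow-free date, lag of
# families other than crane flies is earlier and flatter).
_PITFALL_FAMILIES = {
    "Tipulidae": dict(length=14.0, length_sd=2.0, total=40.0),
    "Chironomidae": dict(length=3.0, length_sd=0.5, total=400.0, lag=15.0, width=10.0),
    "Muscidae": dict(length=6.0, length_sd=1.0, total=60.0, lag=20.0, width=12.0),
    "Carabidae": dict(length=8.0, length_sd=1.5, total=25.0, lag=18.0, width=14.0),
}


def realized_snowmelt(config: ScenarioConfig) -> Dict[int, float]:
    """True 50%-snowmelt day per year: linear trend plus interannual noise."""
    rng = rng_for_table(config.seed, "ndsi", 0)
    years = np.array(config.year_list)
    mean = config.snowmelt_intercept + config.snowmelt_trend * (years - years[0])
    noise = rng.normal(0.0, config.snowmelt_resid_sd, size=len(years))
    return {int(y): float(m + e) for y, m, e in zip(years, mean, noise)}


def snow_probability(config: ScenarioConfig, melt_day: float, days: np.ndarray) -> np.ndarray:
    """Daily probability that a pixel is snow covered.

    The bare fraction follows an asymmetric Gaussian whose spring (left) limb
    crosses 0.5 exactly at ``melt_day``; the snow fraction is its complement.
    """
    days = np.asarray(days, dtype=float)
    mu = melt_day + config.snow_sigma_left * _HALF_WIDTH
    sigma = np.where(days < mu, config.snow_sigma_left, config.snow_sigma_right)
    bare = np.exp(-((days - mu) ** 2) / (2.0 * sigma**2))
    return 1.0 - bare


def gen_ndsi_year(
    config: ScenarioConfig,
    year: int,
    melt_day: Optional[float] = None,
) -> pd.DataFrame:
    """NDSI observations (pixel, day, ndsi) for one season.

    Pixels are classified snow/bare by a Bernoulli draw on the daily snow
    probability (deterministic threshold when ``ndsi_noise`` is 0), then an
    NDSI value is drawn on the matching side of the 0.4 binarization
    threshold so that thresholding recovers the classification exactly.
    """
    config.check_year(year)
    if melt_day is None:
        melt_day = realized_snowmelt(config)[year]
    rng = rng_for_table(config.seed, "ndsi", year)
    days = np.arange(SEASON_DAYS[0], SEASON_DAYS[1] + 1)
    prob = snow_probability(config, melt_day, days)

    day_grid, pixel_grid = np.meshgrid(days, np.arange(config.n_pixels))
    p = np.broadcast_to(prob, day_grid.shape)
    if config.ndsi_noise > 0:
        snow = rng.random(day_grid.shape) < p
        u = rng.random(day_grid.shape)
    else:
        snow = p >= 0.5
        u = np.full(day_grid.shape, 0.5)
    ndsi = np.where(snow, 0.4 + 0.6 * u, 0.4 * u * 0.999)
    return pd.DataFrame(
        {
            "pixel": pixel_grid.ravel(),
            "day": day_grid.ravel(),
            "ndsi": ndsi.ravel(),
            "year": year,
        }
    )


def gen_local_survey(
    config: ScenarioConfig, year: int, melt_day: Optional[float] = None
) -> pd.DataFrame:
    """Local snow-cover survey: percent cover every 2 days through melt-out."""
    config.check_year(year)
    if melt_day is None:
        melt_day = realized_snowmelt(config)[year]
    rng = rng_for_table(config.seed, "local_survey", year)
    days = np.arange(int(melt_day) - 20, int(melt_day) + 25, 2)
    cover = 100.0 * snow_probability(config, melt_day, days)
    noise_sd = 3.0 if config.ndsi_noise > 0 else 0.0
    cover = np.clip(cover + rng.normal(0.0, noise_sd, size=len(days)), 0.0, 100.0)
    return pd.DataFrame({"year": year, "date": days, "cover": cover})


def gen_chick_cohort(
    config: ScenarioConfig,
    year: int,
    n_broods: Optional[int] = None,
    truth: Optional[ScenarioTruth] = None,
    snowmelt: Optional[Dict[int, float]] = None,
) -> pd.DataFrame:
    """Longitudinal chick biometrics for one breeding season.

    Hatch dates are Normal(hatch_mean, hatch_sd) and shared within a brood.
    Per-chick growth-rate deviations are Normal(0, sd_k) per trait.  Growth
    is depressed multiplicatively by ``condition_slope_per_rhd`` x relative
    hatch date, which is exactly what the chick condition index measures.
    """
    config.check_year(year)
    n_broods = config.n_broods_per_year if n_broods is None else n_broods
    if n_broods < 1:
        raise ValueError("n_broods must be >= 1")
    if snowmelt is None:
        snowmelt = realized_snowmelt(config)
    melt = snowmelt[year]
    rng = rng_for_table(config.seed, "chicks", year)

    rows = []
    for b in range(n_broods):
        brood_id = f"{year}-B{b:03d}"
        hatch = rng.normal(config.hatch_mean, config.hatch_sd)
        rhd = hatch - melt
        known = rng.random() < config.known_age_fraction
        if truth is not None:
            truth.hatch_by_brood[brood_id] = float(hatch)
        for c in range(config.chicks_per_brood):
            chick_id = f"{brood_id}-C{c}"
            sex = int(rng.random() < 0.5)
            deviations = {
                trait: float(rng.normal(0.0, gp.sd_k))
                for trait, gp in config.growth_params.items()
            }
            if truth is not None:
                truth.k_deviation_by_chick[chick_id] = deviations
            n_caps = rng.integers(1, 4)
            ages = np.sort(rng.choice(np.arange(0, 22), size=n_caps, replace=False))
            for age in ages:
                obs = {}
                for trait, gp in config.growth_params.items():
                    size = gp.curve(age, k=gp.k + deviations[trait])
                    size = size * (1.0 + config.condition_slope_per_rhd * rhd)
                    obs[trait] = size + rng.normal(0.0, gp.sd_resid)
                p10 = max(0.0, 1.5 + 2.2 * age + rng.normal(0.0, 0.8))
                temp3d = 6.0 + 0.05 * (hatch + age - 190.0) + rng.normal(0.0, 2.0)
                rows.append(
                    {
                        "chick_id": chick_id,
                        "brood_id": brood_id,
                        "year": year,
                        "hatch_day": hatch,
                        "capture_day": hatch + float(age),
                        "age": float(age),
                        "age_known": known,
                        "bill": obs["bill"],
                        "tarsus": obs["tarsus"],
                        "p10": p10,
                        "mass": obs["mass"],
                        "sex": sex,
                        "temp3d": temp3d,
                    }
                )
    return pd.DataFrame(rows)


def _emergence_profile(days_after: np.ndarray, lag: float, width: float) -> np.ndarray:
    """Unnormalized daily emergence intensity, zero before snow-free date."""
    prof = np.exp(-((days_after - lag) ** 2) / (2.0 * width**2))
    prof[days_after < 0] = 0.0
    return prof


def gen_pitfall_season(
    config: ScenarioConfig,
    year: int,
    n_stations: Optional[int] = None,
    truth: Optional[ScenarioTruth] = None,
    snowmelt: Optional[Dict[int, float]] = None,
    n_daily_stations: int = 5,
) -> pd.DataFrame:
    """Pitfall catches with station-specific snow-free dates.

    Crane-fly emergence at a station peaks ``cranefly_peak_lag`` days after
    its snow-free date, with station-level lag jitter ``cranefly_peak_sd``.
    A few stations are emptied daily, the rest every 5 days.
    """
    config.check_year(year)
    n_stations = config.n_stations if n_stations is None else n_stations
    if n_stations < 1:
        raise ValueError("n_stations must be >= 1")
    if snowmelt is None:
        snowmelt = realized_snowmelt(config)
    melt = snowmelt[year]
    rng = rng_for_table(config.seed, "pitfalls", year)

    rows = []
    for s in range(n_stations):
        snowfree = melt + rng.normal(0.0, config.station_snowfree_sd)
        if truth is not None:
            truth.station_snowfree[(year, s)] = float(snowfree)
        interval = 1 if s < n_daily_stations else 5
        station_lag = config.cranefly_peak_lag + rng.normal(0.0, config.cranefly_peak_sd)
        season = np.arange(0, 56)  # day index after snow-free date
        for family, spec_ in _PITFALL_FAMILIES.items():
            lag = station_lag if family == "Tipulidae" else spec_["lag"]
            width = 5.0 if family == "Tipulidae" else spec_["width"]
            # intensity at day centers: day index d spans [d, d+1)
            prof = _emergence_profile(season.astype(float) + 0.5, lag, width)
            lam = spec_["total"] * prof / max(prof.sum(), 1e-12)
            daily = rng.poisson(lam)
            for start in range(0, 55, interval):
                count = int(daily[start : start + interval].sum())
                if count == 0:
                    continue
                length = float(
                    np.clip(
                        rng.normal(spec_["length"], spec_["length_sd"] / np.sqrt(count)),
                        0.5,
                        None,
                    )
                )
                rows.append(
                    {
                        "station": s,
                        "year": year,
                        "snowfree_day": snowfree,
                        "interval_end": snowfree + start + interval,
                        "interval_days": interval,
                        "family": family,
                        "count": count,
                        "mean_length_mm": length,
                    }
                )
    return pd.DataFrame(rows)


def _diet_alpha(config: ScenarioConfig, cranefly_mean: float) -> Tuple[list, np.ndarray]:
    """Dirichlet base measure over 7 key families + a sub-threshold remainder."""
    others = _OTHER_FAMILY_WEIGHTS
    other_total = sum(others.values())
    rest = max(1.0 - cranefly_mean - 0.008, 1e-3)  # 0.008 -> excluded-taxon bin
    names = ["Tipulidae"] + list(others) + ["other"]
    means = np.array(
        [cranefly_mean] + [rest * w / other_total for w in others.values()] + [0.008]
    )
    return names, means / means.sum()


def gen_fecal_diet(
    config: ScenarioConfig,
    year: int,
    n_samples: int = 26,
    truth: Optional[ScenarioTruth] = None,
) -> pd.DataFrame:
    """Brood/date-averaged fecal diet fractions (metabarcoding-style)."""
    config.check_year(year)
    rng = rng_for_table(config.seed, "feces", year)
    names, means = _diet_alpha(config, config.diet_mean_midpoint)
    alpha = config.diet_precision * means
    rows = []
    for i in range(n_samples):
        frac = rng.dirichlet(alpha)
        sample = {
            "brood_id": f"{year}-B{i:03d}",
            "year": year,
            "date": config.hatch_mean + rng.integers(2, 18),
        }
        sample.update({f: float(v) for f, v in zip(names, frac)})
        rows.append(sample)
    return pd.DataFrame(rows)


def gen_isotope_data(
    config: ScenarioConfig,
    diet_truth: pd.DataFrame,
    tissue: str = "juvenile_covert",
    rng: Optional[np.random.Generator] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Feather d15N values from per-bird source proportions, plus the source table.

    ``diet_truth`` must carry a ``bird_id`` column and one column per source
    family, each row summing to 1.  The feather value is the
    proportion-weighted source mean shifted by the tissue discrimination
    factor, with source, discrimination, and residual noise.
    """
    families = [s.family for s in config.source_isotopes]
    missing = [f for f in families if f not in diet_truth.columns]
    if missing:
        raise ValueError(f"diet_truth lacks source columns {missing}")
    props = diet_truth[families].to_numpy(dtype=float)
    if not np.allclose(props.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("per-bird source proportions must sum to 1")
    if tissue == "juvenile_covert":
        delta_mean, delta_sd = config.discrimination_juvenile
    elif tissue == "chick_body":
        delta_mean, delta_sd = config.discrimination_chick
    else:
        raise ValueError(f"unknown tissue {tissue!r}")
    if rng is None:
        rng = rng_for_table(config.seed, "isotopes", 0)

    mu = np.array([s.d15n_mean for s in config.source_isotopes])
    sd = np.array([s.d15n_sd for s in config.source_isotopes])
    n = props.shape[0]
    realized_sources = mu + rng.normal(0.0, 1.0, size=(n, len(mu))) * sd
    delta = rng.normal(delta_mean, delta_sd, size=n)
    d15n = (props * (realized_sources + delta[:, None])).sum(axis=1)
    d15n = d15n + rng.normal(0.0, config.feather_resid_sd, size=n)

    feathers = pd.DataFrame(
        {"bird_id": diet_truth["bird_id"].to_numpy(), "tissue": tissue, "d15n": d15n}
    )
    sources = pd.DataFrame(
        {
            "family": families,
            "d15n_mean": mu,
            "d15n_sd": sd,
        }
    )
    return feathers, sources


def _split_cranefly(
    rng: np.random.Generator, config: ScenarioConfig, p_cf: np.ndarray
) -> pd.DataFrame:
    """Full source-proportion vectors given crane-fly fractions."""
    families = [s.family for s in config.source_isotopes]
    others = [f for f in families if f != "Tipulidae"]
    weights = np.array([_OTHER_FAMILY_WEIGHTS.get(f, 0.05) for f in others])
    alpha = 12.0 * weights / weights.sum()
    split = rng.dirichlet(alpha, size=len(p_cf))
    out = pd.DataFrame({"Tipulidae": p_cf})
    for j, f in enumerate(others):
        out[f] = (1.0 - p_cf) * split[:, j]
    return out[families]


def gen_chick_feathers(
    config: ScenarioConfig,
    chicks: pd.DataFrame,
    truth: Optional[ScenarioTruth] = None,
    snowmelt: Optional[Dict[int, float]] = None,
    brood_sd: float = 0.06,
    resid_sd: float = 0.12,
) -> pd.DataFrame:
    """Chick body-feather d15N with a relative-hatch-date diet gradient.

    The crane-fly fraction declines by ``diet_rhd_slope_chicks`` percentage
    points per day of later hatch relative to snowmelt, with a brood-level
    random intercept.
    """
    if snowmelt is None:
        snowmelt = realized_snowmelt(config)
    rng = rng_for_table(config.seed, "isotopes", 1)
    per_chick = chicks.drop_duplicates("chick_id")[
        ["chick_id", "brood_id", "year", "hatch_day"]
    ].reset_index(drop=True)
    rhd = per_chick.apply(lambda r: r["hatch_day"] - snowmelt[int(r["year"])], axis=1)
    brood_effects = {
        b: rng.normal(0.0, brood_sd) for b in sorted(per_chick["brood_id"].unique())
    }
    p_cf = (
        config.diet_mean_midpoint
        + (config.diet_rhd_slope_chicks / 100.0) * (rhd - rhd.mean())
        + per_chick["brood_id"].map(brood_effects)
        + rng.normal(0.0, resid_sd, size=len(per_chick))
    )
    p_cf = np.clip(p_cf.to_numpy(), 0.02, 0.98)
    props = _split_cranefly(rng, config, p_cf)
    props.insert(0, "bird_id", per_chick["chick_id"])
    feathers, _ = gen_isotope_data(config, props, tissue="chick_body", rng=rng)
    feathers["brood_id"] = per_chick["brood_id"].to_numpy()
    feathers["year"] = per_chick["year"].to_numpy()
    feathers["rhd"] = rhd.to_numpy()
    if truth is not None:
        for cid, p in zip(per_chick["chick_id"], p_cf):
            truth.diet_by_bird[cid] = float(p)
    return feathers


def gen_juvenile_biometrics(
    config: ScenarioConfig,
    truth: Optional[ScenarioTruth] = None,
) -> pd.DataFrame:
    """Winter juvenile biometrics generated from the path-model equations.

    Year (Time), snowmelt, crane-fly diet proportion and body size are drawn
    on the standardized scale from ``config.sem_truth``; body size is then
    mapped to mm-scale bill/tarsus/wing with positive loadings, and feather
    d15N is generated from the diet proportions.  The natural-scale mapping
    of the diet and snowmelt columns is chosen so that the marginal year
    slope of the crane-fly fraction equals ``diet_trend`` (pp/yr) and the
    snowmelt slope equals ``diet_snowmelt_effect`` (pp/day).
    """
    rng = rng_for_table(config.seed, "juveniles", 0)
    st = config.sem_truth
    years = np.array(config.year_list)
    time_z = (years - years.mean()) / years.std()

    snow_z_year = (
        st.snowmelt_intercept
        + st.time_to_snowmelt * time_z
        + rng.normal(0.0, st.sigma_snowmelt, len(years))
    )

    # Natural-unit mappings implied by the configured marginal trends.
    sd_year = years.std()
    indirect = st.time_to_diet + st.snowmelt_to_diet * st.time_to_snowmelt
    scale_p = (
        (config.diet_trend / 100.0) * sd_year / indirect if abs(indirect) > 1e-9 else 0.25
    )
    melt_scale = (
        st.snowmelt_to_diet * scale_p * 100.0 / config.diet_snowmelt_effect
        if abs(config.diet_snowmelt_effect) > 1e-9 and abs(st.snowmelt_to_diet) > 1e-9
        else 8.0
    )
    melt_mean = config.snowmelt_intercept + config.snowmelt_trend * (len(years) - 1) / 2.0

    rows = []
    for yi, year in enumerate(years):
        n = config.n_juveniles_per_year
        sex = (rng.random(n) < 0.5).astype(int)  # 0 male, 1 female
        prop_z = (
            st.diet_intercept
            + st.time_to_diet * time_z[yi]
            + st.snowmelt_to_diet * snow_z_year[yi]
            + rng.normal(0.0, st.sigma_diet, n)
        )
        body_z = (
            st.body_intercept
            + st.time_to_body * time_z[yi]
            + st.snowmelt_to_body * snow_z_year[yi]
            + st.diet_to_body * prop_z
            + st.sex_to_body * sex
            + rng.normal(0.0, st.sigma_body, n)
        )
        p_cf = np.clip(config.diet_mean_midpoint + scale_p * prop_z, 0.02, 0.98)
        melt_day = melt_mean + melt_scale * snow_z_year[yi]
        for i in range(n):
            bird = f"J{year}-{i:03d}"
            row = {
                "bird_id": bird,
                "year": int(year),
                "sex": int(sex[i]),
                "snowmelt_day": float(melt_day),
                "body_z": float(body_z[i]),
                "p_cranefly": float(p_cf[i]),
            }
            for trait, (mean, loading, resid) in config.trait_loadings.items():
                row[trait] = float(mean + loading * body_z[i] + rng.normal(0.0, resid))
            rows.append(row)
            if truth is not None:
                truth.diet_by_bird[bird] = float(p_cf[i])
                truth.body_size_by_bird[bird] = float(body_z[i])
    juv = pd.DataFrame(rows)

    props = _split_cranefly(rng, config, juv["p_cranefly"].to_numpy())
    props.insert(0, "bird_id", juv["bird_id"])
    feathers, _ = gen_isotope_data(config, props, tissue="juvenile_covert", rng=rng)
    juv["d15n"] = feathers["d15n"].to_numpy()
    return juv.drop(columns=["body_z", "p_cranefly"])


def generate_scenario(config: ScenarioConfig) -> Tuple[Dict[str, pd.DataFrame], ScenarioTruth]:
    """Generate all seven input tables and the ground-truth record."""
    truth = ScenarioTruth(config=config)
    melt = realized_snowmelt(config)
    truth.snowmelt_by_year = dict(melt)

    field_years = config.year_list[-2:]  # tundra fieldwork: last two seasons
    ndsi = pd.concat(
        [gen_ndsi_year(config, y, melt[y]) for y in config.year_list], ignore_index=True
    )
    survey = pd.concat(
        [gen_local_survey(config, y, melt[y]) for y in field_years], ignore_index=True
    )
    chicks = pd.concat(
        [gen_chick_cohort(config, y, truth=truth, snowmelt=melt) for y in field_years],
        ignore_index=True,
    )
    pitfalls = pd.concat(
        [gen_pitfall_season(config, y, truth=truth, snowmelt=melt) for y in field_years],
        ignore_index=True,
    )
    feces = pd.concat(
        [gen_fecal_diet(config, y, truth=truth) for y in field_years], ignore_index=True
    )
    chick_feathers = gen_chick_feathers(config, chicks, truth=truth, snowmelt=melt)
    juveniles = gen_juvenile_biometrics(config, truth=truth)
    sources = pd.DataFrame(
        {
            "family": [s.family for s in config.source_isotopes],
            "d15n_mean": [s.d15n_mean for s in config.source_isotopes],
            "d15n_sd": [s.d15n_sd for s in config.source_isotopes],
        }
    )
    tables = {
        "ndsi": ndsi,
        "local_survey": survey,
        "chicks": chicks,
        "pitfalls": pitfalls,
        "feces": feces,
        "sources": sources,
        "juveniles": juveniles,
        "chick_feathers": chick_feathers,
    }
    return tables, truth


def write_scenario(config: ScenarioConfig, out_dir) -> ScenarioTruth:
    """Write all tables as CSV plus the truth record as structured text."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables, truth = generate_scenario(config)
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False)
    (out / "truth.json").write_text(truth.to_text())
    return truth
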