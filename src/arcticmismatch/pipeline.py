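"""Pipeline orchestration: simulate -> phenology -> growth -> diet -> mixing -> path model.

Owns file I/O and schema validation so the analysis modules stay purely
in-memory.  A run is driven by a :class:`RunConfig` (either paths to the
seven input tables or an embedded simulation scenario), writes every stage
output as CSV into the output directory, and records a manifest with the
config hash, seeds, and a checksum per output file: rerunning an identical
configuration reproduces identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import diet as diet_mod
from . import growth as growth_mod
from . import mixing as mixing_mod
from . import pathmodel
from . import phenology
from .config import ScenarioConfig, ScenarioTruth, _config_from_jsonable, _config_to_jsonable
from .simulate import generate_scenario

__all__ = ["RunConfig", "ValidationReport", "validate_inputs", "run_pipeline"]

log = logging.getLogger("arcticmismatch")

ALL_STAGES = ("phenology", "growth", "diet", "mixing", "sem")


@dataclass
class RunConfig:
    out_dir: str
    input_paths: Dict[str, str] = field(default_factory=dict)
    simulate: Optional[ScenarioConfig] = None
    stages: Sequence[str] = ALL_STAGES
    seed: int = 1
    ndsi_threshold: float = 0.4
    crossing: float = 0.5
    key_prey_threshold: float = 0.01
    delta_aicc: float = 2.0
    min_condition_age: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.ndsi_threshold < 1:
            raise ValueError("ndsi_threshold must be in (0, 1)")
        if not 0 < self.crossing < 1:
            raise ValueError("crossing must be in (0, 1)")
        if not 0 <= self.key_prey_threshold < 1:
            raise ValueError("key_prey_threshold must be in [0, 1)")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(pathlib.Path(path).read_text())
        sim = raw.pop("simulate", None)
        cfg = cls(
            out_dir=raw.pop("out_dir"),
            input_paths=raw.pop("inputs", {}),
            stages=tuple(raw.pop("stages", ALL_STAGES)),
            **raw,
        )
        if sim is not None:
            base = _config_to_jsonable(ScenarioConfig())
            base.update(sim)
            cfg.simulate = _config_from_jsonable(base)
        return cfg


# ---------------------------------------------------------------- validation

_NUMERIC = (int, float, np.integer, np.floating)

SCHEMAS: Dict[str, dict] = {
    "ndsi": {
        "required": ["pixel", "day", "ndsi"],
        "checks": {"ndsi": lambda s: (s >= 0) & (s <= 1)},
    },
    "local_survey": {
        "required": ["date", "cover"],
        "checks": {"cover": lambda s: (s >= 0) & (s <= 100)},
    },
    "chicks": {
        "required": [
            "chick_id", "brood_id", "year", "capture_day", "age", "age_known",
            "bill", "tarsus", "p10", "mass", "sex",
        ],
        "checks": {
            "sex": lambda s: s.isin([0, 1]),
            "age": lambda s: s.isna() | (s >= 0),
            "bill": lambda s: s.isna() | (s > 0),
            "tarsus": lambda s: s.isna() | (s > 0),
            "mass": lambda s: s.isna() | (s > 0),
        },
    },
    "pitfalls": {
        "required": [
            "station", "year", "snowfree_day", "interval_end", "interval_days",
            "family", "count", "mean_length_mm",
        ],
        "checks": {
            "count": lambda s: s >= 0,
            "mean_length_mm": lambda s: s > 0,
        },
        "row_checks": {
            "interval_end >= snowfree_day": lambda df: df["interval_end"]
            >= df["snowfree_day"],
        },
    },
    "feces": {"required": ["brood_id", "date"], "checks": {}},
    "sources": {
        "required": ["family", "d15n_mean", "d15n_sd"],
        "checks": {"d15n_sd": lambda s: s >= 0},
    },
    "juveniles": {
        "required": ["bird_id", "year", "sex", "bill", "tarsus", "wing", "d15n"],
        "checks": {"sex": lambda s: s.isin([0, 1])},
    },
}


@dataclass
class ValidationReport:
    issues: List[dict] = field(default_factory=list)
    row_counts: Dict[str, int] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.issues

    def add(self, table: str, column: str, message: str, first_row: Optional[int] = None):
        self.issues.append(
            {"table": table, "column": column, "message": message, "first_row": first_row}
        )


def _validate_table(name: str, df: pd.DataFrame, report: ValidationReport) -> None:
    schema = SCHEMAS.get(name)
    if schema is None:
        return
    report.row_counts[name] = len(df)
    for col in schema["required"]:
        if col not in df.columns:
            report.add(name, col, "missing required column")
    for col, check in schema.get("checks", {}).items():
        if col not in df.columns:
            continue
        ok = check(df[col])
        if not ok.all():
            bad = int(np.flatnonzero(~ok.to_numpy())[0])
            report.add(name, col, f"{int((~ok).sum())} invalid values", first_row=bad)
    for label, check in schema.get("row_checks", {}).items():
        ok = check(df)
        if not ok.all():
            bad = int(np.flatnonzero(~ok.to_numpy())[0])
            report.add(name, label, f"{int((~ok).sum())} rows violate {label}", first_row=bad)
    # fecal fractions: family columns in [0, 1], row sums <= 1
    if name == "feces":
        fam_cols = [c for c in df.columns if c not in ("brood_id", "year", "date")]
        for col in fam_cols:
            ok = (df[col] >= 0) & (df[col] <= 1)
            if not ok.all():
                report.add(name, col, "fraction outside [0, 1]",
                           first_row=int(np.flatnonzero(~ok.to_numpy())[0]))
        sums = df[fam_cols].sum(axis=1)
        ok = sums <= 1.0 + 1e-6
        if not ok.all():
            report.add(name, "(fractions)", "row fractions sum above 1",
                       first_row=int(np.flatnonzero(~ok.to_numpy())[0]))


def load_tables(config: RunConfig) -> Dict[str, pd.DataFrame]:
    """Load (or simulate) all declared input tables."""
    if config.simulate is not None:
        tables, truth = generate_scenario(config.simulate)
        tables["_truth"] = truth  # kept in-memory only
        return tables
    tables = {}
    for name, path in config.input_paths.items():
        p = pathlib.Path(path)
        if not p.exists():
            raise FileNotFoundError(f"input table {name!r}: {p} does not exist")
        tables[name] = pd.read_csv(p)
    return tables


def validate_inputs(config: RunConfig) -> ValidationReport:
    """Check every input table against its schema; report counts and violations."""
    tables = load_tables(config)
    report = ValidationReport()
    for name, df in tables.items():
        if name.startswith("_") or not isinstance(df, pd.DataFrame):
            continue
        _validate_table(name, df, report)
    return report


# ------------------------------------------------------------------- stages

def _sha256(path: pathlib.Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: pathlib.Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages end to end; returns the manifest dict.

    Stage outputs land under ``out_dir``; any stage error halts the run with
    the stage name while earlier outputs stay on disk.  A stage whose inputs
    were produced by a toggled-off stage refuses with a clear message.
    """
    out = pathlib.Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = validate_inputs(config)
    if not report.ok:
        raise ValueError(f"input validation failed: {report.issues[:3]}")
    tables = load_tables(config)

    manifest = {
        "config_hash": hashlib.sha256(
            json.dumps(_jsonable_config(config), sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "stages": list(config.stages),
        "row_counts": report.row_counts,
        "outputs": {},
        "results": {},
    }
    state: dict = {}

    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        try:
            _STAGE_FUNCS[stage](config, tables, state, out, manifest)
        except Exception as exc:
            _finish_manifest(manifest, out)
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        log.info("stage %s complete", stage)
    _finish_manifest(manifest, out)
    return manifest


def _finish_manifest(manifest: dict, out: pathlib.Path) -> None:
    for p in sorted(out.glob("*.csv")):
        manifest["outputs"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


def _jsonable_config(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    if config.simulate is not None:
        d["simulate"] = _config_to_jsonable(config.simulate)
    d["stages"] = list(config.stages)
    return d


def _stage_phenology(config, tables, state, out, manifest):
    if "ndsi" not in tables:
        raise ValueError("phenology stage needs the 'ndsi' table")
    ndsi = tables["ndsi"]
    rows = []
    for year, grp in ndsi.groupby("year"):
        binary = phenology.binarize_ndsi(grp, threshold=config.ndsi_threshold)
        fit = phenology.fit_snow_curve(binary, int(year), crossing=config.crossing)
        rows.append(
            {
                "year": int(year),
                "snowmelt_day": fit.snowmelt_day,
                "converged": fit.converged,
                "baseline": fit.baseline,
                "height": fit.height,
                "mu": fit.mu,
                "sigma_l": fit.sigma_l,
                "sigma_r": fit.sigma_r,
            }
        )
    snow = pd.DataFrame(rows)
    trend = phenology.snowmelt_trend(snow[["year", "snowmelt_day"]])
    state["snowmelt_by_year"] = dict(zip(snow["year"], snow["snowmelt_day"]))
    state["snowmelt_trend"] = trend
    manifest["results"]["snowmelt_trend"] = trend
    _write(snow, out / "snowmelt.csv")

    if "local_survey" in tables:
        local = {
            int(y): phenology.local_snowmelt(g)
            for y, g in tables["local_survey"].groupby("year")
        }
        state["local_snowmelt"] = local
        _write(
            pd.DataFrame({"year": list(local), "local_snowmelt_day": list(local.values())}),
            out / "local_snowmelt.csv",
        )


def _stage_growth(config, tables, state, out, manifest):
    for need in ("chicks", "juveniles"):
        if need not in tables:
            raise ValueError(f"growth stage needs the {need!r} table")
    chicks = tables["chicks"].copy()
    juveniles = tables["juveniles"]

    # winter body size: PC1 and its yearly trend
    trend = growth_mod.juvenile_size_trend(juveniles)
    state["juvenile_trend"] = trend
    manifest["results"]["pc1_variance_explained"] = trend["pca"]["variance_explained"]
    manifest["results"]["pc1_trend_per_year"] = trend["comparison"].averaged_coef.get("year_c")
    manifest["results"]["juvenile_trait_trends"] = trend["trait_trends"]
    _write(trend["comparison"].table(), out / "juvenile_size_models.csv")

    # ages for chicks from unknown-age broods, via the 10th-primary calibration
    known = chicks[chicks["age_known"] & chicks["age"].notna()]
    unknown = chicks[~chicks["age_known"]]
    if len(unknown) and len(known) >= 5:
        est = growth_mod.estimate_age_from_p10(
            known[["age", "p10"]], unknown[["chick_id", "brood_id", "p10"]]
        )
        chicks.loc[est.index, "age"] = est["age"]

    snowmelt = state.get("local_snowmelt") or state.get("snowmelt_by_year")
    if snowmelt is None:
        raise ValueError("growth stage needs snowmelt dates; run the phenology stage")

    fits = {}
    for trait, form in (("tarsus", "logistic"), ("mass", "logistic"), ("bill", "von_bertalanffy")):
        A_fixed = (
            growth_mod.asymptote_from_juveniles(juveniles, trait)
            if trait in growth_mod.STRUCTURAL_TRAITS
            else None
        )
        fits[trait] = growth_mod.fit_growth_model(chicks, trait, form, A_fixed=A_fixed)
    state["growth_fits"] = fits
    _write(
        pd.DataFrame(
            [
                {
                    "trait": f.trait, "form": f.form, "A": f.A, "k": f.k, "T": f.T,
                    "sd_k": f.sd_k, "sd_resid": f.sd_resid, "n_chicks": f.n_chicks,
                }
                for f in fits.values()
            ]
        ),
        out / "growth_fits.csv",
    )

    cond, audit = growth_mod.condition_index(
        fits["tarsus"], chicks, min_age=config.min_condition_age
    )
    manifest["results"]["condition_audit"] = audit
    meta = chicks.drop_duplicates("chick_id").set_index("chick_id")
    cond["rhd"] = [
        growth_mod.relative_hatch_date(
            meta.loc[c, "hatch_day"], snowmelt.get(int(meta.loc[c, "year"]))
        )
        for c in cond["chick_id"]
    ]
    cond["temp3d"] = meta.reindex(cond["chick_id"])["temp3d"].to_numpy()
    comparison = growth_mod.condition_regression(cond)
    state["condition_comparison"] = comparison
    state["condition_table"] = cond
    manifest["results"]["condition_rhd_slope"] = comparison.averaged_coef.get("rhd")
    # effect estimate from the best candidate containing RHD, reported even
    # when the selection favours the intercept-only model
    rhd_models = [c for c in comparison.candidates if "rhd" in c.coef]
    if rhd_models:
        best_rhd = min(rhd_models, key=lambda c: c.aicc)
        manifest["results"]["condition_rhd_slope_full_model"] = best_rhd.coef["rhd"]
        manifest["results"]["condition_rhd_slope_full_model_se"] = best_rhd.se["rhd"]
    _write(cond, out / "condition_index.csv")
    _write(comparison.table(), out / "condition_models.csv")


def _stage_diet(config, tables, state, out, manifest):
    for need in ("pitfalls", "feces"):
        if need not in tables:
            raise ValueError(f"diet stage needs the {need!r} table")
    pitfalls, feces = tables["pitfalls"], tables["feces"]
    keys = diet_mod.key_prey(feces, threshold=config.key_prey_threshold)
    keys = keys[keys["family"] != "other"].reset_index(drop=True)
    state["key_prey"] = keys
    _write(keys, out / "key_prey.csv")
    manifest["results"]["cranefly_diet_mean_pct"] = float(
        100.0 * keys.set_index("family").loc["Tipulidae", "mean_fraction"]
    )

    daily = diet_mod.interpolate_daily_biomass(pitfalls)
    _write(daily, out / "daily_biomass.csv")
    families = [f for f in keys["family"] if f in set(daily["family"])]
    ivlev = diet_mod.ivlev_table(feces, daily, families)
    _write(ivlev, out / "ivlev.csv")
    state["ivlev"] = ivlev

    peak = diet_mod.cranefly_peak_timing(pitfalls)
    state["cranefly_peak"] = peak
    manifest["results"]["cranefly_peak_lag_days"] = peak["grand_mean"]
    _write(peak["station_means"], out / "cranefly_station_means.csv")


def _stage_mixing(config, tables, state, out, manifest):
    for need in ("juveniles", "sources"):
        if need not in tables:
            raise ValueError(f"mixing stage needs the {need!r} table")
    juveniles, sources = tables["juveniles"], tables["sources"]
    results = mixing_mod.fit_mixing_models(
        juveniles.rename(columns={"d15n": "d15n"}),
        sources,
        tissue="juvenile_covert",
        seed=config.seed,
    )
    means = mixing_mod.posterior_means_frame(results)
    juv = juveniles.merge(means, on="bird_id")
    state["juvenile_diet"] = juv
    _write(means, out / "juvenile_diet_posteriors.csv")

    if "snowmelt_day" not in juv.columns:
        snow = state.get("snowmelt_by_year")
        if snow is None:
            raise ValueError("mixing stage needs snowmelt days; run the phenology stage")
        juv["snowmelt_day"] = juv["year"].map(snow)
    comparison = mixing_mod.diet_trend_juveniles(juv)
    state["diet_trend"] = comparison
    manifest["results"]["diet_trend_pp_per_year"] = comparison.averaged_coef.get("year_c")
    _write(comparison.table(), out / "diet_trend_models.csv")

    if "chick_feathers" in tables:
        cf = tables["chick_feathers"]
        chick_results = mixing_mod.fit_mixing_models(
            cf, sources, tissue="chick_body", seed=config.seed + 1
        )
        cf = cf.merge(mixing_mod.posterior_means_frame(chick_results), on="bird_id")
        chick_cmp = mixing_mod.diet_vs_hatch_chicks(cf)
        state["chick_diet_comparison"] = chick_cmp
        manifest["results"]["chick_diet_rhd_slope_pp_per_day"] = (
            chick_cmp.averaged_coef.get("rhd_c")
        )
        _write(chick_cmp.table(), out / "chick_diet_models.csv")


def _stage_sem(config, tables, state, out, manifest):
    if "juvenile_diet" not in state:
        raise ValueError("sem stage needs mixing outputs; run the mixing stage")
    if "juvenile_trend" not in state:
        raise ValueError("sem stage needs the growth stage's winter PC1")
    juv = state["juvenile_diet"].copy()
    pca_scores = state["juvenile_trend"]["pca"]["scores"]
    juv = juv.loc[pca_scores.index]
    juv["body"] = pca_scores
    juv["time"] = juv["year"].astype(float)
    juv["prop"] = juv["p_mean"]
    if "snowmelt_day" not in juv.columns:
        juv["snowmelt_day"] = juv["year"].map(state["snowmelt_by_year"])
    juv["snowmelt"] = juv["snowmelt_day"].astype(float)

    data, scaling = pathmodel.standardize(juv[["time", "snowmelt", "prop", "body", "sex"]])
    fit = pathmodel.fit_path_model(data, seed=config.seed)
    state["sem_fit"] = fit
    state["sem_scaling"] = scaling
    summary = fit.summary()
    _write(summary, out / "sem_coefficients.csv")
    manifest["results"]["sem_direction_probabilities"] = {
        r["parameter"]: r["direction_probability"]
        for _, r in summary.iterrows()
        if not r["parameter"].startswith("sigma_")
    }
    check = pathmodel.simulate_refit_check(fit, data, seed=config.seed + 7)
    state["sem_refit_check"] = check
    manifest["results"]["sem_refit_check_pass"] = check["pass"]


_STAGE_FUNCS = {
    "phenology": _stage_phenology,
    "growth": _stage_growth,
    "diet": _stage_diet,
    "mixing": _stage_mixing,
    "sem": _stage_sem,
}
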