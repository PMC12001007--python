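"""Scenario configuration and ground-truth records for the synthetic study system.

The synthetic scenario emulates a two-decade Arctic shorebird study: satellite
snow-index series over the breeding range, chick growth on the tundra, pitfall
sampling of arthropod prey, fecal diet fractions, feather stable isotopes of
juveniles wintering in West Africa, and the causal chain year -> snowmelt ->
diet -> body size that ties them together.

Defaults are the study conditions: 19 years (2003-2021) with snowmelt
advancing by -0.87 d/yr, hatch centred on July 12 (day 193) with SD 4 d,
crane-fly emergence peaking 29 days after station snowmelt, a crane-fly diet
declining by -0.97 percentage points per year, and a -0.24 %/day growth
penalty per day of relative hatch date.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

__all__ = [
    "GrowthParams",
    "SourceIsotope",
    "SemTruth",
    "ScenarioConfig",
    "ScenarioTruth",
    "rng_for_table",
    "TABLE_INDEX",
]

# Sub-seed offsets: one per generated table so any table can be regenerated
# independently of the others.
TABLE_INDEX = {
    "ndsi": 0,
    "local_survey": 1,
    "chicks": 2,
    "pitfalls": 3,
    "feces": 4,
    "isotopes": 5,
    "juveniles": 6,
}


def rng_for_table(seed: int, table: str, entity: int = 0) -> np.random.Generator:
    """Deterministic per-table (and per-year/entity) generator.

    The master seed plus the table index seeds a SeedSequence; ``entity``
    (typically a year) extends the entropy so per-year calls are independent
    yet reproducible in isolation.
    """
    return np.random.default_rng(np.random.SeedSequence([seed + TABLE_INDEX[table], entity]))


@dataclass(frozen=True)
class GrowthParams:
    """Population growth-curve parameters for one trait.

    ``form`` is 'logistic' (size = A / (1 + exp(-k (t - T))), inflection at T
    where size = A/2) or 'von_bertalanffy' (size = A (1 - exp(-k (t - T))),
    T the horizontal placement).  ``sd_k`` is the between-chick SD of the
    additive deviation on growth rate k; ``sd_resid`` the measurement SD in
    trait units.
    """

    form: str
    A: float
    k: float
    T: float
    sd_k: float
    sd_resid: float

    def __post_init__(self) -> None:
        if self.form not in ("logistic", "von_bertalanffy"):
            raise ValueError(f"unknown growth form {self.form!r}")
        if self.A <= 0 or self.k <= 0:
            raise ValueError("A and k must be positive")
        if self.sd_k < 0 or self.sd_resid < 0:
            raise ValueError("SDs must be non-negative")

    def curve(self, age: np.ndarray, k: Optional[float] = None) -> np.ndarray:
        k = self.k if k is None else k
        age = np.asarray(age, dtype=float)
        if self.form == "logistic":
            return self.A / (1.0 + np.exp(-k * (age - self.T)))
        return self.A * (1.0 - np.exp(-k * (age - self.T)))


@dataclass(frozen=True)
class SourceIsotope:
    family: str
    d15n_mean: float
    d15n_sd: float

    def __post_init__(self) -> None:
        if self.d15n_sd < 0:
            raise ValueError("d15n_sd must be >= 0")


@dataclass(frozen=True)
class SemTruth:
    """Generating coefficients of the three-equation path model (standardized scale).

    Snowmelt = snowmelt_intercept + time_to_snowmelt * Time + e
    Diet     = diet_intercept + time_to_diet * Time + snowmelt_to_diet * Snowmelt + e
    Body     = body_intercept + time_to_body * Time + snowmelt_to_body * Snowmelt
               + diet_to_body * Diet + sex_to_body * Sex + e

    with variable-specific Normal error SDs.  Signs encode the causal story:
    snowmelt advances over years, later snowmelt leaves more crane flies for
    chicks, a crane-fly-richer diet grows bigger birds, and females are the
    larger sex.
    """

    time_to_snowmelt: float = -0.55
    snowmelt_intercept: float = 0.0
    time_to_diet: float = -0.16
    snowmelt_to_diet: float = 0.09
    diet_intercept: float = 0.0
    time_to_body: float = -0.15
    snowmelt_to_body: float = 0.12
    diet_to_body: float = 0.22
    sex_to_body: float = 0.50
    body_intercept: float = 0.0
    sigma_snowmelt: float = 0.80
    sigma_diet: float = 0.85
    sigma_body: float = 0.85

    def as_dict(self) -> Dict[str, float]:
        return dataclasses.asdict(self)


DEFAULT_SOURCES: Tuple[SourceIsotope, ...] = (
    # Crane flies carry the lowest d15N of the key prey; the remaining
    # families cluster a few permil higher, which is what makes a
    # single-isotope mixing model informative about the crane-fly fraction.
    SourceIsotope("Tipulidae", 2.0, 0.5),
    SourceIsotope("Chironomidae", 6.0, 0.6),
    SourceIsotope("Muscidae", 7.0, 0.7),
    SourceIsotope("Carabidae", 7.8, 0.6),
    SourceIsotope("Linyphiidae", 8.5, 0.7),
    SourceIsotope("Mycetophilidae", 6.6, 0.6),
    SourceIsotope("Ichneumonidae", 7.4, 0.6),
)

DEFAULT_GROWTH: Dict[str, GrowthParams] = {
    "tarsus": GrowthParams("logistic", A=31.0, k=0.18, T=4.0, sd_k=0.015, sd_resid=0.5),
    "mass": GrowthParams("logistic", A=110.0, k=0.22, T=9.0, sd_k=0.020, sd_resid=3.0),
    "bill": GrowthParams("von_bertalanffy", A=33.0, k=0.06, T=-7.5, sd_k=0.006, sd_resid=0.6),
}


@dataclass(frozen=True)
class ScenarioConfig:
    """All generating parameters of the synthetic study."""

    years: Tuple[int, int] = (2003, 2021)  # inclusive range
    n_pixels: int = 200
    n_broods_per_year: int = 25
    chicks_per_brood: int = 4
    n_stations: int = 45
    n_juveniles_per_year: int = 30

    # Snowmelt phenology (day-of-year scale)
    snowmelt_intercept: float = 175.0  # at the first year of the range
    snowmelt_trend: float = -0.87  # days/year
    snowmelt_resid_sd: float = 7.9  # interannual SD about the trend line
    snow_sigma_left: float = 18.0  # spring limb width of the bare-fraction curve
    snow_sigma_right: float = 45.0  # autumn limb width
    ndsi_noise: float = 1.0  # 0 => deterministic pixel classification

    # Breeding phenology
    hatch_mean: float = 193.0  # July 12
    hatch_sd: float = 4.0
    known_age_fraction: float = 0.6

    # Prey phenology
    cranefly_peak_lag: float = 29.0  # days after station snow-free date
    cranefly_peak_sd: float = 4.9
    station_snowfree_sd: float = 6.0  # spread of station-specific snow-free dates

    # Growth
    growth_params: Dict[str, GrowthParams] = field(default_factory=lambda: dict(DEFAULT_GROWTH))
    condition_slope_per_rhd: float = -0.0024  # fraction of size per day of RHD

    # Diet.  diet_snowmelt_effect is the slope of the crane-fly diet fraction
    # on snowmelt DAY (positive: later melt leaves more crane flies for the
    # chicks; equivalently a 0.29 pp decline per day of earlier snowmelt).
    diet_trend: float = -0.97  # percentage points / year (crane-fly fraction)
    diet_snowmelt_effect: float = 0.29  # percentage points / day of later snowmelt
    diet_mean_midpoint: float = 0.548  # crane-fly diet fraction at mid-study
    diet_rhd_slope_chicks: float = -0.6  # pp per day of later hatch (chick feathers)
    diet_precision: float = 10.0  # Beta precision of between-bird diet spread

    # Isotopes
    source_isotopes: Tuple[SourceIsotope, ...] = DEFAULT_SOURCES
    discrimination_juvenile: Tuple[float, float] = (3.53, 0.30)  # primary coverts
    discrimination_chick: Tuple[float, float] = (3.33, 0.28)  # body feathers
    feather_resid_sd: float = 0.3  # permil, residual measurement noise

    # Winter biometrics / path model
    sem_truth: SemTruth = field(default_factory=SemTruth)
    sex_effect: float = 0.5  # size units (PC1 scale), females larger
    trait_loadings: Dict[str, Tuple[float, float, float]] = field(
        default_factory=lambda: {
            # trait: (mean mm, loading on latent body size, residual SD mm)
            "bill": (33.0, 1.2, 0.9),
            "tarsus": (31.0, 0.9, 0.8),
            "wing": (165.0, 2.4, 2.2),
        }
    )

    seed: int = 20230

    def __post_init__(self) -> None:
        lo, hi = self.years
        if hi - lo + 1 < 2:
            raise ValueError("year range must span at least 2 years")
        if self.n_pixels < 1:
            raise ValueError("n_pixels must be >= 1")
        for name in (
            "snowmelt_resid_sd",
            "hatch_sd",
            "cranefly_peak_sd",
            "station_snowfree_sd",
            "feather_resid_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.diet_mean_midpoint <= 1.0:
            raise ValueError("diet_mean_midpoint must lie in [0, 1]")

    @property
    def year_list(self) -> list:
        return list(range(self.years[0], self.years[1] + 1))

    def check_year(self, year: int) -> None:
        if not (self.years[0] <= year <= self.years[1]):
            raise ValueError(f"year {year} outside configured range {self.years}")


@dataclass
class ScenarioTruth:
    """Record of every realized generating quantity, keyed for recovery tests.

    Fully determined by (ScenarioConfig, seed): regenerating with the same
    config yields a bit-identical record.
    """

    config: ScenarioConfig
    snowmelt_by_year: Dict[int, float] = field(default_factory=dict)
    hatch_by_brood: Dict[str, float] = field(default_factory=dict)
    k_deviation_by_chick: Dict[str, Dict[str, float]] = field(default_factory=dict)
    station_snowfree: Dict[Tuple[int, int], float] = field(default_factory=dict)
    diet_by_bird: Dict[str, float] = field(default_factory=dict)
    body_size_by_bird: Dict[str, float] = field(default_factory=dict)

    def to_text(self) -> str:
        """Serialize as a flat key/value text block (one entry per line)."""
        payload = {
            "config": _config_to_jsonable(self.config),
            "snowmelt_by_year": {str(k): v for k, v in self.snowmelt_by_year.items()},
            "hatch_by_brood": self.hatch_by_brood,
            "k_deviation_by_chick": self.k_deviation_by_chick,
            "station_snowfree": {f"{y}:{s}": v for (y, s), v in self.station_snowfree.items()},
            "diet_by_bird": self.diet_by_bird,
            "body_size_by_bird": self.body_size_by_bird,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_text(cls, text: str) -> "ScenarioTruth":
        payload = json.loads(text)
        config = _config_from_jsonable(payload["config"])
        truth = cls(config=config)
        truth.snowmelt_by_year = {int(k): v for k, v in payload["snowmelt_by_year"].items()}
        truth.hatch_by_brood = payload["hatch_by_brood"]
        truth.k_deviation_by_chick = payload["k_deviation_by_chick"]
        truth.station_snowfree = {
            (int(k.split(":")[0]), int(k.split(":")[1])): v
            for k, v in payload["station_snowfree"].items()
        }
        truth.diet_by_bird = payload["diet_by_bird"]
        truth.body_size_by_bird = payload["body_size_by_bird"]
        return truth


def _config_to_jsonable(cfg: ScenarioConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["growth_params"] = {k: dataclasses.asdict(v) for k, v in cfg.growth_params.items()}
    d["source_isotopes"] = [dataclasses.asdict(s) for s in cfg.source_isotopes]
    d["sem_truth"] = cfg.sem_truth.as_dict()
    return d


def _config_from_jsonable(d: dict) -> ScenarioConfig:
    d = dict(d)
    d["years"] = tuple(d["years"])
    d["growth_params"] = {k: GrowthParams(**v) for k, v in d["growth_params"].items()}
    d["source_isotopes"] = tuple(SourceIsotope(**s) for s in d["source_isotopes"])
    d["sem_truth"] = SemTruth(**d["sem_truth"])
    d["discrimination_juvenile"] = tuple(d["discrimination_juvenile"])
    d["discrimination_chick"] = tuple(d["discrimination_chick"])
    d["trait_loadings"] = {k: tuple(v) for k, v in d["trait_loadings"].items()}
    return ScenarioConfig(**d)
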