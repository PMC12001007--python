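"""Prey availability, selection, and crane-fly peak timing.

Pitfall catches are converted to dry biomass through tiered family-specific
length-biomass power laws, then to daily availability by anchoring each
5-day interval total at its mean sampling date (emptying day - 2.5) divided
by 5, with linear interpolation between anchors.  Diet selection is the
Ivlev electivity index (O - E) / (O + E) of the observed fecal diet fraction
against the availability fraction on the sampling day.  Key prey are
families averaging more than 1% of the diet.  Crane-fly phenology is
summarized per station as the mean number of days after the station
snow-free date at which a crane fly was trapped, compared between years with
a Welch t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AllometryTable",
    "default_allometry",
    "length_to_biomass",
    "interpolate_daily_biomass",
    "ivlev_index",
    "ivlev_table",
    "key_prey",
    "cranefly_peak_timing",
    "biomass_equivalents",
]


@dataclass(frozen=True)
class AllometryTable:
    """Tiered length-biomass coefficients: m = a * L^b (mg dry mass, L in mm).

    Lookup order mirrors field practice: site-specific coefficients first,
    then coefficients borrowed from a fallback Arctic site, then order-level
    relationships.
    """

    site: Dict[str, tuple]
    fallback_site: Dict[str, tuple]
    order_level: Dict[str, tuple]
    family_to_order: Dict[str, str]

    def lookup(self, family: str) -> tuple:
        if family in self.site:
            return (*self.site[family], "site")
        if family in self.fallback_site:
            return (*self.fallback_site[family], "fallback_site")
        order = self.family_to_order.get(family)
        if order is not None and order in self.order_level:
            return (*self.order_level[order], "order")
        raise KeyError(
            f"no length-biomass coefficients for family {family!r} in any tier"
        )


def default_allometry() -> AllometryTable:
    """Illustrative coefficient table (synthetic values, not field-measured).

    The exponents sit in the 2-3 range typical of arthropod length-mass
    relationships; the scales are set so a 14 mm crane fly weighs a few mg
    and a 3 mm midge a fraction of a mg.
    """
    return AllometryTable(
        site={
            "Tipulidae": (0.0048, 2.75),
            "Chironomidae": (0.0025, 3.10),
            "Carabidae": (0.0300, 2.60),
            "Linyphiidae": (0.0400, 2.40),
            "Mycetophilidae": (0.0060, 2.70),
            "Ichneumonidae": (0.0080, 2.50),
        },
        fallback_site={
            "Muscidae": (0.0120, 2.55),
            "Anthomyiidae": (0.0110, 2.55),
            "Scathophagidae": (0.0100, 2.60),
            "Syrphidae": (0.0090, 2.65),
        },
        order_level={
            "Diptera": (0.0100, 2.50),
            "Coleoptera": (0.0250, 2.60),
            "Araneae": (0.0500, 2.40),
        },
        family_to_order={
            "Tipulidae": "Diptera",
            "Chironomidae": "Diptera",
            "Muscidae": "Diptera",
            "Sciaridae": "Diptera",
            "Carabidae": "Coleoptera",
            "Staphylinidae": "Coleoptera",
            "Lycosidae": "Araneae",
        },
    )


def length_to_biomass(
    family: str, length_mm, table: Optional[AllometryTable] = None
) -> np.ndarray:
    """Dry mass (mg) of individuals from a family-specific power law."""
    if table is None:
        table = default_allometry()
    a, b, _tier = table.lookup(family)
    length = np.asarray(length_mm, dtype=float)
    return a * length**b


def interpolate_daily_biomass(
    records: pd.DataFrame,
    table: Optional[AllometryTable] = None,
    blocklist: Sequence[str] = (),
    return_anchors: bool = False,
):
    """Daily biomass (mg/trap/day) per family, averaged over stations.

    Five-day interval totals are anchored at (emptying day - 2.5) and divided
    by 5; daily-interval stations pass through unchanged.  Values between
    anchors are linearly interpolated to integer days, and each day carries
    the family's share of the all-family biomass that day.
    """
    if table is None:
        table = default_allometry()
    df = records[~records["family"].isin(blocklist)].copy()
    mass = np.array(
        [
            float(length_to_biomass(f, l, table)) * c
            for f, l, c in zip(df["family"], df["mean_length_mm"], df["count"])
        ]
    )
    df["biomass_mg"] = mass

    frames: List[pd.DataFrame] = []
    anchor_rows: List[pd.DataFrame] = []
    for (station, family), grp in df.groupby(["station", "family"]):
        grp = grp.sort_values("interval_end")
        interval = grp["interval_days"].to_numpy(dtype=float)
        anchor = grp["interval_end"].to_numpy(dtype=float) - interval / 2.0
        daily_rate = grp["biomass_mg"].to_numpy(dtype=float) / interval
        anchor_rows.append(
            pd.DataFrame(
                {
                    "station": station,
                    "family": family,
                    "anchor_day": anchor,
                    "daily_rate": daily_rate,
                    "interval_days": interval,
                    "interval_total": grp["biomass_mg"].to_numpy(dtype=float),
                }
            )
        )
        day_lo = int(np.floor(grp["interval_end"].min() - grp["interval_days"].max()))
        day_hi = int(np.ceil(grp["interval_end"].max()))
        days = np.arange(day_lo, day_hi + 1)
        if len(anchor) == 1:
            warnings.warn(
                f"single interval for station {station} family {family}; "
                "carrying a constant daily value"
            )
            values = np.full(len(days), daily_rate[0])
        else:
            values = np.interp(days, anchor, daily_rate)
        frames.append(
            pd.DataFrame(
                {"station": station, "family": family, "day": days, "biomass": values}
            )
        )
    daily = pd.concat(frames, ignore_index=True)
    out = daily.groupby(["day", "family"], as_index=False)["biomass"].mean()
    totals = out.groupby("day")["biomass"].transform("sum")
    out["proportion"] = np.where(totals > 0, out["biomass"] / totals, np.nan)
    if return_anchors:
        return out, pd.concat(anchor_rows, ignore_index=True)
    return out


def ivlev_index(O: float, E: float) -> float:
    """Ivlev electivity (O - E) / (O + E); NaN when both proportions are zero."""
    if not (0.0 <= O <= 1.0) or not (0.0 <= E <= 1.0):
        raise ValueError("O and E must lie in [0, 1]")
    if O == 0.0 and E == 0.0:
        return float("nan")
    return (O - E) / (O + E)


def ivlev_table(
    feces: pd.DataFrame,
    daily_biomass: pd.DataFrame,
    families: Sequence[str],
) -> pd.DataFrame:
    """Per-sample, per-family electivity of diet fraction vs availability.

    ``feces`` needs ``brood_id``, ``date`` and one column per family;
    availability E is the interpolated biomass proportion of the family on
    the fecal sampling date.
    """
    avail = daily_biomass.pivot_table(index="day", columns="family", values="proportion")
    rows = []
    for _, sample in feces.iterrows():
        day = int(round(sample["date"]))
        day_use = min(max(day, avail.index.min()), avail.index.max())
        for family in families:
            O = float(sample.get(family, 0.0))
            E = float(avail.loc[day_use].get(family, 0.0))
            if np.isnan(E):
                E = 0.0
            index = ivlev_index(O, E) if not (O == 0.0 and E == 0.0) else np.nan
            rows.append(
                {
                    "brood_id": sample["brood_id"],
                    "date": sample["date"],
                    "family": family,
                    "O": O,
                    "E": E,
                    "ivlev": index,
                }
            )
    return pd.DataFrame(rows)


def key_prey(
    feces: pd.DataFrame,
    families: Optional[Sequence[str]] = None,
    threshold: float = 0.01,
) -> pd.DataFrame:
    """Families whose mean diet fraction exceeds the threshold (default 1%).

    Sorted by mean fraction descending; raises on an empty sample table.
    """
    if len(feces) == 0:
        raise ValueError("no fecal samples")
    if families is None:
        meta = {"brood_id", "year", "date"}
        families = [c for c in feces.columns if c not in meta]
    means = feces[list(families)].mean()
    sems = feces[list(families)].sem()
    out = pd.DataFrame(
        {"family": means.index, "mean_fraction": means.values, "se": sems.values}
    )
    out = out[out["mean_fraction"] > threshold]
    return out.sort_values("mean_fraction", ascending=False, ignore_index=True)


def cranefly_peak_timing(
    records: pd.DataFrame,
    family: str = "Tipulidae",
    bin_width: int = 5,
) -> dict:
    """Crane-fly peak timing relative to station-specific snow-free dates.

    Per station, the mean number of days after its snow-free date at which a
    crane fly was trapped (catch-count weighted, interval midpoints for
    pooled samples); stations without any crane fly are excluded.  The
    abundance profile is binned into [0,5), [5,10), ... day intervals, and
    the per-station metric is compared between years with a Welch t-test.
    Catches dated before the station snow-free day are dropped and counted.
    """
    df = records[records["family"] == family].copy()
    df["days_after"] = (
        df["interval_end"] - df["interval_days"] / 2.0 - df["snowfree_day"]
    )
    n_before = int((df["days_after"] < 0).sum())
    df = df[df["days_after"] >= 0]

    def _station_mean(grp: pd.DataFrame) -> float:
        return float(np.average(grp["days_after"], weights=grp["count"]))

    station_means = (
        df.groupby(["year", "station"])
        .apply(_station_mean, include_groups=False)
        .rename("mean_day")
        .reset_index()
    )

    edges = np.arange(0, df["days_after"].max() + bin_width, bin_width)
    binned = (
        df.groupby(pd.cut(df["days_after"], edges, right=False), observed=True)["count"]
        .sum()
        .rename("count")
        .reset_index()
    )

    result = {
        "station_means": station_means,
        "grand_mean": float(station_means["mean_day"].mean()),
        "grand_sd": float(station_means["mean_day"].std(ddof=1))
        if len(station_means) > 1
        else 0.0,
        "binned_profile": binned,
        "n_dropped_before_snowfree": n_before,
        "t_test": None,
    }
    years = sorted(station_means["year"].unique())
    if len(years) == 2:
        a = station_means.loc[station_means["year"] == years[0], "mean_day"]
        b = station_means.loc[station_means["year"] == years[1], "mean_day"]
        if len(a) >= 2 and len(b) >= 2:
            t, p = stats.ttest_ind(a, b, equal_var=False)
            result["t_test"] = {"t": float(t), "p": float(p), "n": (len(a), len(b))}
        else:
            warnings.warn("a year has fewer than 2 qualifying stations; t-test skipped")
    return result


def biomass_equivalents(prey_mass_mg: float, alternative_mass_mg: float) -> int:
    """How many alternative prey items match one focal prey item, rounded.

    E.g. a 6.56 mg crane fly is worth about 66 non-biting midges of 0.10 mg.
    """
    if alternative_mass_mg <= 0:
        raise ValueError("alternative prey mass must be positive")
    return int(round(prey_mass_mg / alternative_mass_mg))
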