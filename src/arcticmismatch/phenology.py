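"""Snowmelt phenology from satellite snow-index series and ground surveys.

The regional snowmelt date is extracted from binarized NDSI pixel series by
maximum-likelihood fitting of a seasonal snow-fraction curve and solving for
its 50% crossing on the spring limb; the local date comes from linear
interpolation of a ground snow-cover survey; the across-year trend is an
ordinary least-squares fit of snowmelt day on year.

Model.  The bare-ground fraction follows an asymmetric Gaussian
``g(t) = baseline + height * exp(-(t - mu)^2 / (2 sigma^2))`` with separate
spring (``sigma_l``, t < mu) and autumn (``sigma_r``, t >= mu) widths; the
snow fraction is ``1 - g(t)``.  Daily snow counts are Binomial(n_pixels,
snow fraction), so pixel counts weight the likelihood.  The snowmelt day is
the day the snow fraction falls below 0.5 while bare ground rises through
0.5 on the spring limb, solved by bisection to 0.01 day.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "binarize_ndsi",
    "fit_snow_curve",
    "local_snowmelt",
    "snowmelt_trend",
    "compare_local_regional",
    "SnowCurveFit",
    "NoCrossingError",
]

NDSI_SNOW_THRESHOLD = 0.4


class NoCrossingError(ValueError):
    """The fitted or surveyed snow series never crosses the 50% level."""


@dataclass
class SnowCurveFit:
    year: int
    baseline: float
    height: float
    mu: float
    sigma_l: float
    sigma_r: float
    loglik: float
    snowmelt_day: Optional[float]
    converged: bool

    def bare_fraction(self, day) -> np.ndarray:
        day = np.asarray(day, dtype=float)
        sigma = np.where(day < self.mu, self.sigma_l, self.sigma_r)
        return self.baseline + self.height * np.exp(
            -((day - self.mu) ** 2) / (2.0 * sigma**2)
        )

    def snow_fraction(self, day) -> np.ndarray:
        return 1.0 - self.bare_fraction(day)


def binarize_ndsi(obs: pd.DataFrame, threshold: float = NDSI_SNOW_THRESHOLD) -> pd.DataFrame:
    """Classify each (pixel, day) NDSI value as snow (>= threshold) or bare.

    Row count is preserved; values outside [0, 1] raise with the offending
    row indices named.
    """
    ndsi = obs["ndsi"].to_numpy(dtype=float)
    bad = np.flatnonzero((ndsi < 0.0) | (ndsi > 1.0) | ~np.isfinite(ndsi))
    if bad.size:
        shown = ", ".join(str(i) for i in bad[:10])
        raise ValueError(
            f"{bad.size} NDSI values outside [0, 1] (row indices: {shown}"
            + ("..." if bad.size > 10 else ")")
        )
    out = obs[["pixel", "day"]].copy()
    out["snow"] = (ndsi >= threshold).astype(int)
    return out


def _daily_counts(binary: pd.DataFrame):
    grouped = binary.groupby("day")["snow"].agg(["sum", "count"])
    days = grouped.index.to_numpy(dtype=float)
    k = grouped["sum"].to_numpy(dtype=float)
    n = grouped["count"].to_numpy(dtype=float)
    return days, k, n


def _negloglik(params, days, k, n):
    baseline, height, mu, log_sl, log_sr = params
    if not (0.0 <= baseline < 0.5) or not (0.0 < height <= 1.0 - baseline):
        return 1e12
    sl, sr = np.exp(log_sl), np.exp(log_sr)
    sigma = np.where(days < mu, sl, sr)
    bare = baseline + height * np.exp(-((days - mu) ** 2) / (2.0 * sigma**2))
    snow = np.clip(1.0 - bare, 1e-9, 1.0 - 1e-9)
    return -float(np.sum(k * np.log(snow) + (n - k) * np.log(1.0 - snow)))


def fit_snow_curve(binary: pd.DataFrame, year: int, crossing: float = 0.5) -> SnowCurveFit:
    """Fit the seasonal snow-fraction curve and extract the snowmelt day.

    Requires >= 20 day points including both snowy and bare observations.
    Raises :class:`NoCrossingError` when the series is all snow or all bare;
    a non-converged optimization is returned flagged, without a snowmelt day.
    """
    days, k, n = _daily_counts(binary)
    if len(days) < 20:
        raise ValueError(f"need >= 20 day points, got {len(days)}")
    frac_snow = k / n
    if np.all(frac_snow > 0.999) or np.all(frac_snow < 0.001):
        raise NoCrossingError("series is entirely snow or entirely bare; no 50% crossing")

    # Moment-based initials: interpolated raw 50% crossing of the bare
    # fraction for mu placement, quartile spreads for the widths.
    bare = 1.0 - frac_snow
    cross0 = _first_upcrossing(days, bare, 0.5)
    if cross0 is None:
        cross0 = days[np.argmax(bare)]
    peak_day = days[np.argmax(bare)]
    sl0 = max((peak_day - cross0) / np.sqrt(2 * np.log(2)), 2.0)
    x0 = np.array([0.01, 0.98, cross0 + sl0 * np.sqrt(2 * np.log(2)), np.log(sl0), np.log(30.0)])

    res = optimize.minimize(
        _negloglik,
        x0,
        args=(days, k, n),
        method="Nelder-Mead",
        options=dict(xatol=1e-6, fatol=1e-8, maxiter=4000),
    )
    # quasi-Newton polish from the simplex optimum
    polish = optimize.minimize(
        _negloglik, res.x, args=(days, k, n), method="Powell",
        options=dict(xtol=1e-8, ftol=1e-10, maxiter=2000),
    )
    if polish.fun <= res.fun:
        res = polish
    baseline, height, mu, log_sl, log_sr = res.x
    fit = SnowCurveFit(
        year=year,
        baseline=float(baseline),
        height=float(height),
        mu=float(mu),
        sigma_l=float(np.exp(log_sl)),
        sigma_r=float(np.exp(log_sr)),
        loglik=-float(res.fun),
        snowmelt_day=None,
        converged=bool(res.success or res.fun < 1e11),
    )
    if fit.converged:
        fit.snowmelt_day = _solve_crossing(fit, days[0], crossing)
    return fit


def _first_upcrossing(x: np.ndarray, y: np.ndarray, level: float) -> Optional[float]:
    below = y < level
    for i in range(len(x) - 1):
        if below[i] and not below[i + 1]:
            f = (level - y[i]) / (y[i + 1] - y[i])
            return float(x[i] + f * (x[i + 1] - x[i]))
    return None


def _solve_crossing(fit: SnowCurveFit, first_day: float, crossing: float) -> float:
    """Bisection for the bare-fraction up-crossing on [first day, mu], 0.01-day tol."""
    lo, hi = float(first_day), float(fit.mu)
    f = lambda t: fit.bare_fraction(t) - crossing
    if f(hi) < 0.0:
        raise NoCrossingError("fitted curve never reaches the 50% bare level")
    if f(lo) > 0.0:
        raise NoCrossingError("fitted curve is already half bare at the season start")
    while hi - lo > 0.01:
        mid = 0.5 * (lo + hi)
        if f(mid) < 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def local_snowmelt(survey: pd.DataFrame) -> float:
    """First linearly interpolated day at which surveyed snow cover drops below 50%.

    ``survey`` needs ``date`` and ``cover`` (percent) columns; refreeze is
    allowed, only the earliest down-crossing counts.
    """
    df = survey.sort_values("date")
    days = df["date"].to_numpy(dtype=float)
    cover = df["cover"].to_numpy(dtype=float)
    if np.any((cover < 0) | (cover > 100)):
        raise ValueError("cover values must lie in [0, 100]")
    if cover[0] < 50.0:
        return float(days[0])
    for i in range(len(days) - 1):
        if cover[i] >= 50.0 and cover[i + 1] < 50.0:
            f = (cover[i] - 50.0) / (cover[i] - cover[i + 1])
            return float(days[i] + f * (days[i + 1] - days[i]))
    raise NoCrossingError("survey never drops below 50% cover")


def snowmelt_trend(days_by_year: pd.DataFrame | dict) -> dict:
    """OLS trend of snowmelt day on year: slope (days/yr) with SE, and intercept."""
    if isinstance(days_by_year, dict):
        df = pd.DataFrame(
            {"year": list(days_by_year), "snowmelt_day": list(days_by_year.values())}
        )
    else:
        df = days_by_year
    if len(df) < 3:
        raise ValueError("need >= 3 years for a trend")
    import statsmodels.api as sm

    x = sm.add_constant(df["year"].to_numpy(dtype=float))
    fit = sm.OLS(df["snowmelt_day"].to_numpy(dtype=float), x).fit()
    return {
        "slope": float(fit.params[1]),
        "slope_se": float(fit.bse[1]),
        "intercept": float(fit.params[0]),
        "n_years": int(len(df)),
    }


def compare_local_regional(local_days: Sequence[float], regional_days: Sequence[float]) -> dict:
    """Report the mean offset between ground-survey and satellite snowmelt days.

    The offset is reported only — downstream analyses keep using the
    satellite-derived dates.
    """
    local = np.asarray(local_days, dtype=float)
    regional = np.asarray(regional_days, dtype=float)
    if local.shape != regional.shape:
        raise ValueError("paired arrays required")
    diff = local - regional
    out = {
        "mean_offset_days": float(diff.mean()),
        "sd_offset_days": float(diff.std(ddof=1)) if len(diff) > 1 else 0.0,
        "n": int(len(diff)),
    }
    if len(diff) > 2:
        out["pearson_r"] = float(np.corrcoef(local, regional)[0, 1])
    return out
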