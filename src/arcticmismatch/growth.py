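"""Chick growth modelling and winter body-size analysis.

Population growth curves (logistic for tarsus and body mass, von Bertalanffy
for bill and the structural PC1) are fitted to longitudinal chick biometrics
by nonlinear least squares with an additive per-chick deviation on the growth
rate ``k``, shrunk by a Normal(0, sd_k^2) penalty whose scale is estimated by
marginal maximum likelihood (a linearized nonlinear mixed model).  Structural
traits take a fixed asymptote from winter juvenile means; body-mass models
estimate the asymptote freely.

The chick condition index is (observed - predicted) / predicted size at age,
with predictions from the population curve (chick deviations excluded), so a
consistently slow chick stays consistently negative.  Condition is regressed
on relative hatch date and 3-day pre-capture temperature with year and chick
grouping intercepts, compared by AICc with the uninformative-parameter rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize

from .modelselect import CandidateFit, ModelComparison, compare_models

__all__ = [
    "logistic_curve",
    "von_bertalanffy_curve",
    "GrowthFit",
    "fit_growth_model",
    "condition_index",
    "relative_hatch_date",
    "condition_regression",
    "estimate_age_from_p10",
    "body_size_pc1",
    "juvenile_size_trend",
    "asymptote_from_juveniles",
]

STRUCTURAL_TRAITS = {"bill", "tarsus", "pc1"}
MIN_CONDITION_AGE = 2.0  # chicks younger than this survive mostly on yolk


def logistic_curve(age, A, k, T):
    age = np.asarray(age, dtype=float)
    return A / (1.0 + np.exp(-k * (age - T)))


def von_bertalanffy_curve(age, A, k, T):
    age = np.asarray(age, dtype=float)
    return A * (1.0 - np.exp(-k * (age - T)))


_CURVES = {"logistic": logistic_curve, "von_bertalanffy": von_bertalanffy_curve}


def _curve_dk(form: str, age: np.ndarray, A: float, k: float, T: float) -> np.ndarray:
    """Derivative of the growth curve with respect to k."""
    age = np.asarray(age, dtype=float)
    if form == "logistic":
        e = np.exp(-k * (age - T))
        return A * (age - T) * e / (1.0 + e) ** 2
    return A * (age - T) * np.exp(-k * (age - T))


@dataclass
class GrowthFit:
    trait: str
    form: str
    A: float
    k: float
    T: float
    sd_k: float
    sd_resid: float
    k_deviations: Dict[str, float]
    A_fixed: bool
    loglik: float
    converged: bool
    n_chicks: int
    n_obs: int

    def predict(self, age, chick_id: Optional[str] = None) -> np.ndarray:
        """Population prediction; pass a chick id to include its k deviation."""
        k = self.k + (self.k_deviations.get(chick_id, 0.0) if chick_id else 0.0)
        return _CURVES[self.form](age, self.A, k, self.T)


def _initial_kT(form: str, age: np.ndarray, y: np.ndarray, A: float) -> Tuple[float, float]:
    """Closed-form initials by linearizing the curve at known asymptote."""
    y = np.clip(y, 1e-6, A * (1.0 - 1e-6))
    if form == "logistic":
        z = np.log(A / y - 1.0)  # = -k (t - T)
    else:
        z = np.log(1.0 - y / A)  # = -k (t - T)
    slope, intercept = np.polyfit(age, z, 1)
    k0 = max(-slope, 1e-3)
    T0 = intercept / k0 if k0 > 0 else 0.0
    return k0, T0


def _population_nls(
    form: str, age: np.ndarray, y: np.ndarray, A_fixed: Optional[float]
) -> Tuple[float, float, float]:
    curve = _CURVES[form]
    if A_fixed is not None:
        k0, T0 = _initial_kT(form, age, y, A_fixed)
        res = optimize.least_squares(
            lambda p: curve(age, A_fixed, p[0], p[1]) - y,
            x0=[k0, T0],
            bounds=([1e-6, -200.0], [5.0, 200.0]),
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        return A_fixed, float(res.x[0]), float(res.x[1])
    A0 = 1.1 * float(np.max(y))
    k0, T0 = _initial_kT(form, age, y, A0)
    res = optimize.least_squares(
        lambda p: curve(age, p[0], p[1], p[2]) - y,
        x0=[A0, k0, T0],
        bounds=([1e-6, 1e-6, -200.0], [np.inf, 5.0, 200.0]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    return float(res.x[0]), float(res.x[1]), float(res.x[2])


def fit_growth_model(
    records: pd.DataFrame,
    trait: str,
    form: str,
    A_fixed: Optional[float] = None,
    min_chicks: int = 10,
) -> GrowthFit:
    """Fit a population growth curve with per-chick growth-rate deviations.

    ``records`` needs ``chick_id``, ``age`` and a column named ``trait``.
    Structural traits (bill, tarsus, pc1) require ``A_fixed`` taken from
    winter juvenile means; body mass estimates the asymptote freely.
    """
    if form not in _CURVES:
        raise ValueError(f"unknown growth form {form!r}")
    if trait in STRUCTURAL_TRAITS and A_fixed is None:
        raise ValueError(
            f"structural trait {trait!r} requires a fixed asymptote from winter juveniles"
        )
    df = records.dropna(subset=[trait, "age"])
    chicks = df["chick_id"].to_numpy()
    unique_chicks, chick_idx = np.unique(chicks, return_inverse=True)
    if len(unique_chicks) < min_chicks:
        raise ValueError(f"need >= {min_chicks} chicks, got {len(unique_chicks)}")
    age = df["age"].to_numpy(dtype=float)
    y = df[trait].to_numpy(dtype=float)
    n_obs = len(y)
    n_chicks = len(unique_chicks)

    A, k, T = _population_nls(form, age, y, A_fixed)
    curve = _CURVES[form]
    resid = y - curve(age, A, k, T)
    mse = float(np.mean(resid**2))
    if mse < 1e-16:
        # Degenerate noiseless data: the population curve is exact.
        return GrowthFit(
            trait=trait, form=form, A=A, k=k, T=T, sd_k=0.0, sd_resid=0.0,
            k_deviations={c: 0.0 for c in unique_chicks}, A_fixed=A_fixed is not None,
            loglik=np.inf, converged=True, n_chicks=n_chicks, n_obs=n_obs,
        )

    free_A = A_fixed is None
    delta = np.zeros(n_chicks)

    def marginal_nll(theta, delta_lin):
        if free_A:
            A_, k_, T_, log_sdk, log_sig = theta
        else:
            k_, T_, log_sdk, log_sig = theta
            A_ = A_fixed
        if A_ <= 0 or k_ <= 0:
            return 1e12
        sdk2 = np.exp(2.0 * log_sdk)
        sig2 = np.exp(2.0 * log_sig)
        k_obs = k_ + delta_lin[chick_idx]
        f = curve(age, A_, k_obs, T_)
        g = _curve_dk(form, age, A_, k_obs, T_)
        r = y - f + g * delta_lin[chick_idx]
        gg = np.bincount(chick_idx, weights=g * g, minlength=n_chicks)
        gr = np.bincount(chick_idx, weights=g * r, minlength=n_chicks)
        rr = np.bincount(chick_idx, weights=r * r, minlength=n_chicks)
        ni = np.bincount(chick_idx, minlength=n_chicks)
        denom = sig2 + sdk2 * gg
        quad = (rr - sdk2 * gr**2 / denom) / sig2
        logdet = ni * np.log(sig2) + np.log1p(sdk2 * gg / sig2)
        return 0.5 * float(np.sum(quad + logdet + ni * np.log(2 * np.pi)))

    sd0 = np.sqrt(mse)
    theta = ([A] if free_A else []) + [k, T, np.log(max(0.05 * k, 1e-4)), np.log(sd0)]
    theta = np.array(theta)
    converged = True
    for _ in range(3):  # PNLS-style relinearization rounds
        res = optimize.minimize(
            marginal_nll, theta, args=(delta,), method="Nelder-Mead",
            options=dict(xatol=1e-7, fatol=1e-8, maxiter=6000),
        )
        converged = bool(res.success)
        theta = res.x
        if free_A:
            A_, k_, T_, log_sdk, log_sig = theta
        else:
            k_, T_, log_sdk, log_sig = theta
            A_ = A_fixed
        sdk2, sig2 = np.exp(2.0 * log_sdk), np.exp(2.0 * log_sig)
        k_obs = k_ + delta[chick_idx]
        f = curve(age, A_, k_obs, T_)
        g = _curve_dk(form, age, A_, k_obs, T_)
        r = y - f + g * delta[chick_idx]
        gg = np.bincount(chick_idx, weights=g * g, minlength=n_chicks)
        gr = np.bincount(chick_idx, weights=g * r, minlength=n_chicks)
        delta = sdk2 * gr / (sig2 + sdk2 * gg)

    if not converged:
        raise RuntimeError(
            f"growth model for {trait!r} did not converge; best iterate "
            f"k={k_:.4f}, T={T_:.3f}, A={A_:.3f}"
        )
    return GrowthFit(
        trait=trait, form=form, A=float(A_), k=float(k_), T=float(T_),
        sd_k=float(np.sqrt(sdk2)), sd_resid=float(np.sqrt(sig2)),
        k_deviations={c: float(d) for c, d in zip(unique_chicks, delta)},
        A_fixed=A_fixed is not None, loglik=-marginal_nll(theta, delta),
        converged=True, n_chicks=n_chicks, n_obs=n_obs,
    )


def condition_index(
    fit: GrowthFit,
    records: pd.DataFrame,
    min_age: float = MIN_CONDITION_AGE,
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Per-observation condition index (obs - pred) / pred on the population curve.

    Chicks younger than ``min_age`` days are excluded (they still run on
    yolk), and rows with missing age or trait value are skipped; the audit
    dict reports row counts in/kept/dropped by reason.
    """
    audit = {"n_in": len(records)}
    df = records.copy()
    missing = df["age"].isna() | df[fit.trait].isna()
    audit["n_missing"] = int(missing.sum())
    df = df[~missing]
    young = df["age"] < min_age
    audit["n_excluded_age"] = int(young.sum())
    df = df[~young]
    audit["n_kept"] = len(df)

    pred = fit.predict(df["age"].to_numpy(dtype=float))
    value = (df[fit.trait].to_numpy(dtype=float) - pred) / pred
    out = df[["chick_id", "brood_id", "year", "capture_day", "age"]].copy()
    out["trait"] = fit.trait
    out["predicted"] = pred
    out["value"] = value
    return out.reset_index(drop=True), audit


def relative_hatch_date(hatch_day: float, snowmelt_day: Optional[float]) -> float:
    """Relative hatch date: hatch day minus the year's (local) snowmelt day."""
    if snowmelt_day is None or not np.isfinite(snowmelt_day):
        raise ValueError("snowmelt day missing for this year")
    return float(hatch_day) - float(snowmelt_day)


def _mixed_candidate(
    data: pd.DataFrame, terms: Tuple[str, ...], response: str = "value"
) -> CandidateFit:
    import statsmodels.formula.api as smf

    rhs = " + ".join(terms) if terms else "1"
    formula = f"{response} ~ {rhs}"
    n_groups = data["chick_id"].nunique()
    n_years = data["year"].nunique()
    if n_groups < 2 or n_years < 2:
        raise _SingularGrouping()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            formula,
            data,
            groups="year",
            re_formula="1",
            vc_formula={"chick": "0 + C(chick_id)"},
        )
        fit = model.fit(reml=False, method=["lbfgs", "powell"])
    fe = fit.fe_params
    n_params = len(fe) + 2 + 1  # fixed effects + two variance components + residual
    return CandidateFit(
        terms=frozenset(terms),
        loglik=float(fit.llf),
        n_params=n_params,
        n_obs=len(data),
        coef={t: float(fe[t]) for t in terms},
        se={t: float(fit.bse_fe[t]) for t in terms},
    )


class _SingularGrouping(Exception):
    pass


def _ols_candidate(data: pd.DataFrame, terms: Tuple[str, ...], response: str = "value") -> CandidateFit:
    import statsmodels.formula.api as smf

    rhs = " + ".join(terms) if terms else "1"
    fit = smf.ols(f"{response} ~ {rhs}", data).fit()
    return CandidateFit(
        terms=frozenset(terms),
        loglik=float(fit.llf),
        n_params=len(fit.params) + 1,
        n_obs=len(data),
        coef={t: float(fit.params[t]) for t in terms},
        se={t: float(fit.bse[t]) for t in terms},
    )


def condition_regression(
    condition: pd.DataFrame,
    min_obs: int = 30,
    hinge_at: Optional[float] = None,
) -> ModelComparison:
    """AICc comparison of condition ~ {nothing, RHD, temperature, both}.

    ``condition`` needs ``value``, ``rhd``, ``temp3d``, ``year`` and
    ``chick_id`` columns; year and chick enter as grouping intercepts.  With
    ``hinge_at`` set, an experimental hinge term max(0, rhd - hinge_at) joins
    the candidate set (late-hatching chicks may pay a disproportionate
    penalty); it is exploratory and off by default.
    """
    df = condition.dropna(subset=["value", "rhd", "temp3d"]).copy()
    if len(df) < min_obs:
        raise ValueError(f"need >= {min_obs} observations, got {len(df)}")
    term_sets = [(), ("rhd",), ("temp3d",), ("rhd", "temp3d")]
    if hinge_at is not None:
        df["rhd_hinge"] = np.maximum(0.0, df["rhd"] - hinge_at)
        term_sets.append(("rhd", "rhd_hinge"))
    candidates = []
    for terms in term_sets:
        try:
            candidates.append(_mixed_candidate(df, terms))
        except _SingularGrouping:
            warnings.warn(
                "singular grouping structure; falling back to fixed effects only"
            )
            candidates.append(_ols_candidate(df, terms))
    return compare_models(candidates)


def estimate_age_from_p10(
    calibration: pd.DataFrame,
    query: pd.DataFrame,
    min_pairs: int = 5,
) -> pd.DataFrame:
    """Estimate chick age from 10th-primary length, averaged per brood.

    ``calibration`` holds known-age (age, p10) pairs; ``query`` needs
    ``chick_id``, ``brood_id`` and ``p10``.  Predictions outside the
    calibration p10 range are flagged as extrapolation.
    """
    calib = calibration.dropna(subset=["age", "p10"])
    if len(calib) == 0:
        raise ValueError("empty calibration set")
    if len(calib) < min_pairs:
        raise ValueError(f"need >= {min_pairs} calibration pairs, got {len(calib)}")
    slope, intercept = np.polyfit(
        calib["p10"].to_numpy(dtype=float), calib["age"].to_numpy(dtype=float), 1
    )
    out = query[["chick_id", "brood_id", "p10"]].copy()
    out["age_individual"] = intercept + slope * out["p10"].to_numpy(dtype=float)
    lo, hi = calib["p10"].min(), calib["p10"].max()
    out["extrapolated"] = (out["p10"] < lo) | (out["p10"] > hi)
    out["age"] = out.groupby("brood_id")["age_individual"].transform("mean")
    return out


def body_size_pc1(biometrics: pd.DataFrame, traits: Sequence[str] = ("bill", "tarsus", "wing")) -> dict:
    """PC1 of unit-variance-scaled structural traits, signed so bigger = bigger bird.

    Returns scores (indexed like the complete-case rows), loadings, percent
    variance explained, and the centering/scaling needed to project new data.
    """
    df = biometrics.dropna(subset=list(traits))
    n_dropped = len(biometrics) - len(df)
    if len(df) < 3:
        raise ValueError("need >= 3 complete rows for a PCA")
    X = df[list(traits)].to_numpy(dtype=float)
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    if np.any(scale == 0):
        raise ValueError("a trait has zero variance")
    Z = (X - mean) / scale
    _, s, vt = np.linalg.svd(Z, full_matrices=False)
    loadings = vt[0]
    if loadings.sum() < 0:  # sign convention: larger PC1 = larger bird
        loadings = -loadings
    scores = Z @ loadings
    var_explained = 100.0 * s[0] ** 2 / np.sum(s**2)
    return {
        "scores": pd.Series(scores, index=df.index, name="pc1"),
        "loadings": dict(zip(traits, loadings)),
        "variance_explained": float(var_explained),
        "mean": dict(zip(traits, mean)),
        "scale": dict(zip(traits, scale)),
        "n_dropped": n_dropped,
    }


def project_pc1(pca: dict, values: Dict[str, float]) -> float:
    """Project a new trait vector (e.g. juvenile means) onto a fitted PC1."""
    z = np.array(
        [(values[t] - pca["mean"][t]) / pca["scale"][t] for t in pca["loadings"]]
    )
    return float(z @ np.array(list(pca["loadings"].values())))


def asymptote_from_juveniles(juveniles: pd.DataFrame, trait: str) -> float:
    """Fixed growth asymptote: mean of the male- and female-specific juvenile means.

    Averaging the per-sex means corrects for unequal sample sizes between
    the sexes.
    """
    sex_means = juveniles.groupby("sex")[trait].mean()
    if len(sex_means) == 0:
        raise ValueError("no juvenile data for asymptote")
    return float(sex_means.mean())


def juvenile_size_trend(juveniles: pd.DataFrame) -> dict:
    """Yearly trend in winter body size (PC1 and single traits) with sex.

    Returns the PCA, an AICc comparison of PC1 ~ {year, sex} candidates, and
    per-trait year slopes.
    """
    pca = body_size_pc1(juveniles)
    df = juveniles.loc[pca["scores"].index].copy()
    df["pc1"] = pca["scores"]
    df["year_c"] = df["year"] - df["year"].mean()
    term_sets = [(), ("year_c",), ("sex",), ("year_c", "sex"), ("year_c", "sex", "year_c:sex")]
    candidates = [_ols_candidate(df, t, response="pc1") for t in term_sets]
    comparison = compare_models(candidates)

    import statsmodels.formula.api as smf

    per_trait = {}
    for trait in ("bill", "tarsus", "wing"):
        fit = smf.ols(f"{trait} ~ year_c + sex", df).fit()
        per_trait[trait] = {
            "slope": float(fit.params["year_c"]),
            "se": float(fit.bse["year_c"]),
        }
    return {"pca": pca, "comparison": comparison, "trait_trends": per_trait}


def percent_scale(values: Iterable[float], reference: float) -> np.ndarray:
    """Express sizes as percent of a reference prediction (display only)."""
    if reference == 0:
        raise ValueError("reference size must be nonzero")
    return 100.0 * np.asarray(list(values), dtype=float) / reference
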