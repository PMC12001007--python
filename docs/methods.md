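# Methods

This note documents the models implemented in `arcticmismatch`, the choices
made where the design was genuinely open, and what the synthetic study does
and does not emulate.

## Snowmelt phenology

Pixel-level NDSI values in [0, 1] are classified as snow when NDSI ≥ 0.4
(the established MODIS snow threshold; the boundary counts as snow).  For
each year the daily snow counts k_t of n_t valid pixels are modelled as
Binomial(n_t, s(t)) with

    s(t) = 1 − g(t),   g(t) = baseline + height · exp(−(t − μ)² / 2σ²),

where g is the bare-ground fraction with separate spring (σ_L, t < μ) and
autumn (σ_R, t ≥ μ) widths — an asymmetric Gaussian that rises through
spring, peaks in mid-summer and decays as new snow arrives.  Constraints:
baseline ∈ [0, 0.5), height ≤ 1 − baseline, σ > 0 (log-parameterized).  The
likelihood uses pixel counts as weights, so duplicating every pixel leaves
the fit unchanged.  Optimization is Nelder–Mead from moment-based initials
(raw 50% crossing and quartile spreads) with a derivative-free Powell
polish; the snowmelt day is the 0.5 up-crossing of g on [first day, μ],
solved by bisection to 0.01 d.  For the parameterization above the crossing
has the closed form μ − σ_L √(2 ln(height / (0.5 − baseline))), which the
tests use as an independent oracle.  A fit is "no crossing" when the series
is all snow or all bare.  The ground-survey date is the first linearly
interpolated day below 50% cover; the camp-vs-satellite offset is reported
by a comparison utility but never applied, and all downstream analyses use
the satellite dates.  The across-year trend is OLS of snowmelt day on year.

One curve is fitted per year on pooled pixel fractions (not per pixel); the
trend estimator only needs the yearly summary.

## Chick growth and condition

Growth curves: logistic A / (1 + e^{−k(t−T)}) for tarsus and body mass
(inflection at T where size = A/2), von Bertalanffy A(1 − e^{−k(t−T)}) for
bill, with T the horizontal placement.  Structural traits use a fixed
asymptote: the mean of the male- and female-specific winter-juvenile means
(sex-balanced against unequal sample sizes); body mass estimates A freely
because winter mass is not representative of the growth asymptote.

Repeated captures are handled by an additive per-chick deviation δᵢ on k
with Normal(0, sd_k²) shrinkage.  Estimation is a linearized nonlinear
mixed model: given (k, T, A), the model is linearized in δ around the
current per-chick estimates, each chick's marginal likelihood is evaluated
in closed form (Woodbury identity, one random effect per chick), and
(k, T, [A], log sd_k, log σ) are optimized by Nelder–Mead, alternating with
BLUP updates of δ for three relinearization rounds.  Noise-free data
(MSE < 1e−16 after plain nonlinear least squares) short-circuit to the
exact NLS solution with sd_k = 0.  Initial (k, T) come from the closed-form
linearization of each curve at known asymptote.

The condition index is (observed − predicted)/predicted at the chick's age,
with predictions from the **population** curve (chick deviations excluded),
so repeated captures of a slow chick stay consistently negative.  Chicks
younger than 2 days are excluded (yolk-sac phase) and every exclusion is
counted in an audit record.  Being a ratio, the index is invariant to
measurement units.

Condition is regressed on relative hatch date (RHD = hatch day − snowmelt
day) and mean temperature over the 3 days before capture, with year and
chick grouping intercepts (chicks nested in years; ML, not REML, so AICc is
comparable across fixed-effect structures).  The candidate set is all
subsets of {RHD, temperature}; an optional hinge term max(0, RHD − 10),
off by default and flagged experimental, probes the possibility that the
penalty only starts some days after snowmelt.  With a degenerate grouping
structure the fit degrades to fixed effects with a warning.

Note an intentional property of the full synthetic scenario: the generator
depresses sizes multiplicatively by slope × RHD while the fixed-asymptote
fit assumes the undepressed asymptote, so the population fit absorbs part
of the mean depression into a lower apparent k.  Estimator-recovery tests
therefore generate from the growth model itself (depression off), while the
condition regression — whose estimand is the *relative* penalty per day —
recovers the configured slope unbiasedly at scale under the full scenario.

## Model comparison

AICc = −2 logL + 2k + 2k(k+1)/(n−k−1).  Models within 2 ΔAICc of the best
are competitive; a model is excluded as carrying uninformative parameters
when a strictly nested simpler candidate sits within 2 AICc units of it
(the extra parameter failed to buy a 2-unit improvement).  The reported
"selected" model is the lowest-AICc member of the surviving set; when
several survive, coefficients are model-averaged with renormalized AICc
weights and unconditional SEs (within-model variance plus between-model
spread).  Under a null effect this protocol selects the intercept-only
model in well over 80% of replicates while a strong effect keeps the
richer model.

## Prey availability and selection

Arthropod length is converted to dry mass by family-specific power laws
m = a·L^b looked up in three tiers (site-specific, fallback Arctic site,
order-level), mirroring how such coefficient tables are assembled in
practice.  The shipped default table is **synthetic/illustrative** — the
exponents are in the 2–3 range typical of arthropod length–mass scaling —
because site-measured coefficients are study-specific data.

Five-day pitfall totals are anchored at the mean sampling date (emptying
day − 2.5) and divided by 5 to daily rates; daily stations pass through
unchanged.  Conservation (rate × interval = interval total, to 1e−9) holds
at this anchoring step by construction and is what the tests assert; values
on days between anchors are linear interpolations and are not separately
mass-conserving.  Per-day family proportions of total biomass feed the
Ivlev electivity (O − E)/(O + E) against fecal diet fractions, with E
matched to the fecal sampling date.  Key prey are families averaging >1%
of the diet.  Crane-fly peak timing is the per-station catch-weighted mean
number of days after that station's snow-free date (stations with no crane
flies excluded; catches dated before snow-free dropped and counted), binned
at [0,5), [5,10), … for the profile, and compared between years with a
Welch (unequal-variance) t-test — the conservative default when only
"t-test" is specified.

## Isotope mixing

Per bird, feather δ¹⁵N is modelled as

    δ ~ Normal( Σₖ pₖ(μₖ + Δ),  √( Σₖ pₖ²(σₖ² + σ_Δ²) + σ_res² ) ),

the standard single-tracer formulation with proportion-weighted source and
discrimination variance.  Priors: flat Dirichlet(1, …, 1) on p;
half-Normal(0, 0.25 ‰) on σ_res.  The residual scale deserves a note: each
bird is fitted to a *single* feather value, so σ_res is not identifiable
from the data and its prior must be anchored at the scale of analytical
replicate error in feather δ¹⁵N (≈0.1–0.3 ‰).  A diffuse residual prior
would let the likelihood go flat and shrink every bird's diet estimate
toward the prior mean 1/K, destroying the very trend the model exists to
measure.  Discrimination factors are tissue-specific inputs: 3.53 ± 0.30 ‰
for juvenile primary coverts, 3.33 ± 0.28 ‰ for chick body feathers.

Sampling is random-walk Metropolis on additive-log-ratio coordinates of the
simplex plus log σ_res (the flat Dirichlet becomes a Σ log pₖ Jacobian),
4 chains × 10,000 iterations, first 1,000 discarded, step sizes adapted
toward 30% acceptance during burn-in only.  All birds run vectorized in a
single pass.  Convergence is monitored by split-chain R̂ on every
proportion (threshold 1.05); non-converged fits are flagged but summarized.
For ≤3 sources a dense-grid posterior is the independent oracle; for two
sources with vanishing SDs the posterior mean approaches the algebraic
solution p₁ = (δ − Δ − μ₂)/(μ₁ − μ₂).

With one isotope and seven sources the posterior is diffuse by
construction; posterior SDs are always reported, and regressions of
posterior means on covariates are attenuated by the posterior shrinkage.
The recovery tests therefore compare fitted slopes against the realized
signal times a shrinkage factor measured in-test (the regression of
posterior means on true proportions), rather than pretending the posterior
mean were an unbiased point estimate.

Diet-trend models: winter juveniles get OLS candidates over subsets of
{year, snowmelt, sex} plus a two-way-interaction model (joint year+snowmelt
models are skipped with a warning when |r| > 0.99); tundra chicks get
{∅, RHD, year, RHD+year} with a brood grouping intercept, degrading to
fixed effects for a single brood or a boundary-singular brood variance.
Slopes are reported in percentage points per unit.

## Path model

Three recursive linear equations on standardized variables (sex stays a
0/1 indicator):

    Snowmelt = a₁ + b·Time + ε₁
    Diet     = a₂ + b·Time + b·Snowmelt + ε₂
    Body     = a₃ + b·Time + b·Snowmelt + b·Diet + b·Sex + ε₃

with variable-specific Normal errors.  Because every variable is observed,
the joint posterior factorizes over equations: coefficients are Gibbs-
sampled (conditionally Normal under Normal(0, 10²) priors — effectively
flat on the z-score scale) and each log error SD takes a Metropolis step
under a half-Normal(0, 5) prior.  Schedule: 4 chains × 10,000 iterations,
1,000 burn-in, matching the mixing model for uniformity; split-chain R̂
threshold 1.05.  The unit of observation is the individual juvenile;
snowmelt enters as the year-level mean without uncertainty, and the diet
proportion as the per-bird posterior mean from the mixing stage (plug-in
treatment for both; the posterior SD of the diet estimate is not
propagated, which is documented as a limitation).  Effects are summarized
as direction probabilities max(P(b>0), P(b<0)).

The reliability check simulates datasets of the original size from the
posterior means (keeping Time and Sex), refits, and requires every
coefficient's bias — averaged over 3 replicate simulations — to stay
within 2 refit posterior SDs.  Averaging over a few replicates keeps the
2-SD band while suppressing single-simulation noise: with ~13 parameters a
one-shot rule would fail by chance in roughly a third of healthy runs,
whereas the replicate-averaged verdict is stable across seeds and still
fails when a generating coefficient is genuinely wrong.

## The synthetic study

The generator's defaults are the study conditions: 19 years (2003–2021),
200 NDSI pixels, snowmelt starting at day 175 and advancing −0.87 d/yr with
7.9 d interannual SD (chosen so the trend SE matches the ±0.33 scale of a
two-decade Arctic record); hatch ~ Normal(July 12, 4 d), constant across
years, so relative hatch date deteriorates as snowmelt advances; 25 broods
of 4 chicks per year with 1–3 captures each in the last two seasons;
crane-fly emergence peaking 29.0 d after each station's snow-free date with
4.9 d between-station SD across 45 stations (5 emptied daily, 40 every
5 days); a crane-fly fecal diet share of 54.8% with six companion families
between 1% and 20%; source δ¹⁵N signatures with crane flies lowest (2 ‰ vs
6–8.5 ‰); and 30 juveniles per year whose body size is generated directly
from the path-model equations, then mapped to bill/tarsus/wing with
positive loadings and sexual dimorphism (females larger).  The natural-unit
mappings of the diet and snowmelt columns are derived from the configured
marginal trends (−0.97 pp/yr over years; 0.29 pp per day of later
snowmelt), so the standardized path coefficients and the headline slopes
are mutually consistent.  Chick feathers carry a −0.6 pp/day RHD gradient
with a brood random intercept.

Determinism: one master seed; each table derives its own sub-seed (master +
table index, extended by year), so any table regenerates independently and
bit-identically.  Dates are integer day-of-year within a named season; no
calendar arithmetic crosses years.

What the generator does **not** emulate: cloud gaps and water masking in
the satellite series, spatial autocorrelation among pixels and stations,
migration/survival selection between fledging and winter capture (so the
chick-level and juvenile-level size declines are not forced to agree, and
real-data discrepancies attributable to selective mortality are out of
reach), metabarcoding read noise, and within-brood size correlation beyond
the shared hatch date (exposed as brood-level random effects where
relevant).  Passing recovery tests therefore demonstrate correctness of
the estimators under the assumed data structure, not robustness to those
real-data complications.

## Problem sizes and runtime choices

Tests run the full 19-year scenario for phenology (≈200 pixels × 211 days),
two field seasons for growth and diet, 570 juveniles through the mixing
model (vectorized, seconds), and 25 replicates for the path-model coverage
suite at n = 200 with a shortened (3,000-iteration) schedule; the
full 4 × 10,000 schedule is used wherever a result is reported or an
oracle is compared.  The complete pipeline runs in ≈20 s and the whole
test suite in a few minutes on one CPU.
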