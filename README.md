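# arcticmismatch

Tools for asking whether a warming Arctic is shrinking migratory shorebirds
through a **demand–resource mismatch** during chick growth.  The package
implements the full inference chain linking advancing snowmelt on high-Arctic
breeding grounds to declining juvenile body size measured on the wintering
grounds:

```
year  →  snowmelt date  →  crane-fly share of the chick diet  →  body size
                                  (sex → body size)
```

It is written for quantitative ecologists who have (or want to emulate) the
typical data of such a study: satellite snow-index series, longitudinal chick
biometrics, pitfall-trap catches, fecal metabarcoding diet fractions, prey
δ¹⁵N signatures, and feather δ¹⁵N of winter-caught juveniles.

## What's inside

| module | what it does |
| --- | --- |
| `simulate` | generates all seven input tables with known ground truth, so every estimator has a parameter-recovery test |
| `phenology` | binarizes NDSI at 0.4, fits an asymmetric-Gaussian seasonal snow-fraction curve by binomial maximum likelihood, extracts the 50% snowmelt day, fits the across-year trend |
| `growth` | logistic / von Bertalanffy growth curves with a per-chick deviation on growth rate *k* (Normal shrinkage, marginal ML); chick condition index (obs − pred)/pred; age from 10th-primary length; AICc condition regressions; winter body-size PC1 |
| `diet` | tiered length→biomass power laws, daily biomass interpolation (interval totals anchored at emptying − 2.5 d, ÷ 5), Ivlev electivity (O − E)/(O + E), >1% key-prey rule, crane-fly peak timing with Welch t-test |
| `mixing` | Bayesian single-isotope mixing model: δ¹⁵N ~ N(Σₖ pₖ(μₖ + Δ), √(Σₖ pₖ²(σₖ² + σ_Δ²) + σ_res²)) with a flat Dirichlet prior on the simplex, tissue-specific discrimination (3.53 ± 0.30 ‰ juvenile coverts, 3.33 ± 0.28 ‰ chick body feathers), 4 chains × 10,000 MCMC draws |
| `pathmodel` | three-equation recursive Bayesian path model on standardized variables, coefficient direction probabilities P(|λ| > 0), simulate-refit reliability check |
| `pipeline` | schema validation, stage orchestration, manifest with checksums; thin `arcticmismatch` CLI |

## A worked example

```bash
python examples/snowmelt_phenology.py
```

fits the snow curve for each of 19 synthetic years and prints

```
2020: snowmelt day  157.1  (truth  157.1)
2021: snowmelt day  168.4  (truth  168.4)

Trend: -0.62 +/- 0.37 days/year over 19 years
```

i.e. the 50% crossing is recovered to a fraction of a day per year, and
snowmelt advances significantly across the two decades.  The other examples
follow the same pattern, one per capability:

```bash
python examples/chick_growth_condition.py    # growth curves + condition ~ hatch date
python examples/prey_selection_phenology.py  # key prey, Ivlev, crane-fly peak
python examples/diet_mixing.py               # feather d15N -> diet fractions + trend
python examples/path_model.py                # the Bayesian path model + refit check
python examples/full_pipeline.py             # everything end to end
```

`prey_selection_phenology.py`, for instance, reports that crane flies are
trapped on average `29.6 ± 5.2` days after their station's snow-free date —
the lag that makes late-hatching chicks miss the peak — and
`chick_growth_condition.py` shows the AICc selection keeping relative hatch
date in the condition model, with each day of later hatch costing a fraction
of a percent of structural size.

The same chain runs from the shell:

```bash
arcticmismatch simulate --out data/ --seed 1
arcticmismatch run --config run.yaml
```

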