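"""Fit the three-equation Bayesian path model and run the reliability check.

Standardized year, snowmelt, crane-fly diet fraction and body size (plus a
0/1 sex indicator) enter a recursive system

    year -> snowmelt -> diet -> body size  (sex -> body size)

sampled by MCMC; coefficients are summarized with direction probabilities,
and the fit is validated by simulating a same-size dataset from the
posterior means and refitting.
"""

import numpy as np

from arcticmismatch import ScenarioConfig, fit_path_model, simulate_refit_check, standardize
from arcticmismatch.config import ScenarioTruth
from arcticmismatch.simulate import gen_juvenile_biometrics

cfg = ScenarioConfig()
truth = ScenarioTruth(config=cfg)
juv = gen_juvenile_biometrics(cfg, truth=truth)
juv["prop"] = juv["bird_id"].map(truth.diet_by_bird)  # demo: true diet fractions
juv["body"] = juv["bird_id"].map(truth.body_size_by_bird)
juv["time"] = juv["year"].astype(float)
juv["snowmelt"] = juv["snowmelt_day"]

data, scaling = standardize(juv[["time", "snowmelt", "prop", "body", "sex"]])
fit = fit_path_model(data, seed=11)
print(fit.summary().to_string(index=False, float_format=lambda v: f"{v: .3f}"))
print(
    "\nEach row is a path coefficient on the standardized scale; the direction\n"
    "probability is max(P(coef > 0), P(coef < 0)).  Negative time->snowmelt\n"
    "means advancing snowmelt; positive diet->body means crane-fly-rich diets\n"
    "grow bigger birds."
)

check = simulate_refit_check(fit, data, seed=12)
print(f"\nSimulate-refit reliability check: {'PASS' if check['pass'] else 'FAIL'} "
      f"(all coefficient biases within 2 posterior SDs over "
      f"{check['n_replicates']} replicate simulations)")
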