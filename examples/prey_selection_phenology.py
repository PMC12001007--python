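"""Key prey, electivity, and how long after snowmelt crane flies peak.

Generates pitfall catches and fecal diet fractions, identifies key prey
(>1% of diet), computes daily biomass availability, Ivlev electivity, and
the per-station crane-fly peak timing relative to snow-free dates.
"""

import warnings

import pandas as pd

from arcticmismatch import ScenarioConfig, cranefly_peak_timing, ivlev_index, key_prey
from arcticmismatch.diet import interpolate_daily_biomass, ivlev_table
from arcticmismatch.simulate import gen_fecal_diet, gen_pitfall_season, realized_snowmelt

cfg = ScenarioConfig()
melt = realized_snowmelt(cfg)
years = cfg.year_list[-2:]
pitfalls = pd.concat(
    [gen_pitfall_season(cfg, y, snowmelt=melt) for y in years], ignore_index=True
)
feces = pd.concat([gen_fecal_diet(cfg, y) for y in years], ignore_index=True)

keys = key_prey(feces)
keys = keys[keys["family"] != "other"]
print("Key prey (mean diet fraction > 1%):")
print(keys.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    daily = interpolate_daily_biomass(pitfalls)
iv = ivlev_table(feces, daily, ["Tipulidae", "Chironomidae"])
for fam, grp in iv.groupby("family"):
    print(f"Mean Ivlev electivity {fam}: {grp['ivlev'].mean():+.2f} "
          "(positive = selected beyond availability)")

peak = cranefly_peak_timing(pitfalls)
print(
    f"\nCrane flies were trapped on average {peak['grand_mean']:.1f} +/- "
    f"{peak['grand_sd']:.1f} days after the station snow-free date."
)
t = peak["t_test"]
print(f"Between-year Welch t-test: t = {t['t']:.2f}, p = {t['p']:.2f} "
      "(no shift in peak timing between the two field seasons)")
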