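"""Individual-level selection: KDE home ranges and the weighted RSF.

Simulates GPS telemetry for 10 resident animals (females on smaller
home-range kernels than males) whose fixes are thinned by an exponential
selection function, estimates 95% KDE home ranges, tests the male/female
area contrast with a Kruskal-Wallis rank test, and fits the
distribution-weighted exponential RSF (each animal contributes equal
total weight).
"""

import numpy as np
import pandas as pd

from habconn import covariates as cov
from habconn import homerange as hr
from habconn import synth
from habconn.geodata import PointSet

cfg = synth.LandscapeConfig(nrows=200, ncols=200, seed=77)
landcover = synth.generate_landcover(cfg)
lines = synth.generate_lines(cfg)
grids = {
    "forest_7km2": cov.window_proportion(landcover, synth.CLASS_CODES["forest"], 7.0),
    "road_density": cov.road_density(lines, landcover, 7.0),
}
stack = cov.scale_covariates(cov.CovariateStack(grids))

beta = {"forest_7km2": 1.0, "road_density": -1.0}
parts = []
for sex, sigma, seed in (("F", 300.0, 4), ("M", 480.0, 5)):
    truth = synth.TruthModel(beta=beta, hr_sigma_m=sigma)
    tel = synth.generate_telemetry(stack, truth, n_individuals=5,
                                   fixes_per_individual=80, seed=seed)
    df = tel.df.copy()
    df["sex"] = sex
    df["individual_id"] = sex + df["individual_id"].astype(str)
    df["id"] = sex + df["id"].astype(str)
    parts.append(PointSet(df))
telemetry = PointSet.concat(parts)

kept, report = hr.filter_individuals(telemetry, min_fixes=30)
print(f"{len(report)} collared animals, {len(kept.individuals())} kept (>30 fixes)")

print("\n95% KDE home ranges:")
ranges, avail_parts = [], []
for k, ind in enumerate(kept.individuals()):
    fixes = kept.subset(kept.df["individual_id"] == ind)
    h = hr.kde_home_range(fixes, isopleth=0.95, individual_id=str(ind))
    ranges.append(h)
    avail_parts.append(hr.sample_availability(h, len(fixes), seed=50 + k,
                                              within=stack.geometry()))
    print(f"  {h.individual_id}: sex {h.sex}, {h.n_fixes} fixes, "
          f"{h.area_km2:.2f} km^2")

areas = np.array([h.area_km2 for h in ranges])
sexes = np.array([h.sex for h in ranges])
print(f"\nmean area: females {areas[sexes == 'F'].mean():.2f} km^2, "
      f"males {areas[sexes == 'M'].mean():.2f} km^2")
H, df_, p = hr.kruskal_wallis(areas, sexes)
print(f"Kruskal-Wallis area-by-sex: chi-squared = {H:.3f}, df = {df_}, p = {p:.3f}")

available = PointSet.concat(avail_parts)
fit = hr.fit_weighted_rsf(kept, available, stack, form="exponential_RSF")
print("\ndistribution-weighted exponential RSF (w(x) = exp(beta.x)):")
for term in fit.terms:
    print(f"  {term:14s} beta = {fit.coef[term]:+.3f} (SE {fit.se[term]:.3f})"
          f"  true {beta[term]:+.1f}")
print(f"CAIC = {fit.caic:.1f} on {fit.n_effective} used+available rows")
print("(magnitudes are attenuated relative to the generative truth because"
      "\navailability is drawn within home ranges that already sit in"
      "\npreferred habitat; the signs are the recoverable signal)")

curve = hr.rss_use_curve(fit, available, stack, "forest_7km2")
lo, hi = curve["smooth"].iloc[0], curve["smooth"].iloc[-1]
print(f"\nuse-probability curve along forest share: smooth rises {lo:.2f} -> {hi:.2f}"
      "\n(the curve depicts probability of use under current availability)")
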