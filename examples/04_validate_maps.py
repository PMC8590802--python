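"""Disperser-based validation of competing connectivity maps.

Draws candidate-disperser locations concentrated in high-current
corridors, matches each with 3 random available points, scores every
point with the decile of each candidate map, fits a random-intercept
logistic model per map and averages the maps with AICc weights.
"""

import numpy as np
from scipy import ndimage

from habconn import synth
from habconn.connectivity import (
    NodeRegion,
    ResistanceTransform,
    cumulative_current,
    grid_to_graph,
    quantile_classify,
    suitability_to_resistance,
)
from habconn.geodata import Grid
from habconn.validation import build_matched_sets, fit_mixed_logistic, rank_and_average_maps

rng = np.random.default_rng(6)
f = ndimage.gaussian_filter(rng.normal(size=(100, 100)), 8, mode="wrap")
H = Grid((f - f.min()) / (f.max() - f.min()) * 0.9 + 0.05, 30.0)
regions = []
for k, (i0, j0) in enumerate([(5, 5), (90, 90), (5, 90), (90, 5), (47, 47)]):
    m = np.zeros((100, 100), bool)
    m[i0:i0 + 5, j0:j0 + 5] = True
    regions.append(NodeRegion(f"r{k}", m))

current, deciles = {}, {}
for tr in (ResistanceTransform("linear"), ResistanceTransform("exponential", 2.0),
           ResistanceTransform("exponential", 8.0)):
    cm = cumulative_current(grid_to_graph(suitability_to_resistance(H, tr)), regions)
    current[tr.label] = cm.grid
    deciles[tr.label] = quantile_classify(cm.grid, 10)

dispersers = synth.generate_dispersers(current["linear"], 46, preference=3.0, seed=7)
matched = build_matched_sets(dispersers, deciles, buffer_m=600, n_avail=3, seed=8)
print(f"{matched.table['used'].sum()} used locations, "
      f"{len(matched.table)} rows total (1 used + 3 available each)")

fits = [fit_mixed_logistic(matched, nm) for nm in matched.map_names]
print("\nmodel selection over resistance shapes "
      "(used/available ~ decile + (1 | location)):")
for f_ in sorted(fits, key=lambda f: f.aicc):
    print(f"  {f_.map_name:10s} slope {f_.slope:+.3f}  LL {f_.llf:8.3f}"
          f"  AICc {f_.aicc:7.2f}")

weights, averaged = rank_and_average_maps(fits, current)
print("\nAICc weights:", {k: round(v, 3) for k, v in weights.items()})
print("averaged map mean (unit-mean normalized):",
      round(float(averaged.valid_values().mean()), 3))
print("\nA positive slope means dispersers sit in higher connectivity"
      "\ndeciles than matched random points; near-equal weights mean the"
      "\nthree resistance shapes predict dispersers equally well.")
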