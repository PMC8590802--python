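# habconn

Two-level habitat selection and circuit-theory connectivity for
recolonizing wildlife populations.

When a carnivore population re-expands into a human-dominated landscape,
managers need to know three things: which habitat the *population*
selects at broad scales, what *individuals* select within their home
ranges, and where the landscape will let dispersers move next. `habconn`
is a tested, reusable pipeline for exactly that workflow, built for
landscape/movement ecologists working with occurrence records, GPS
telemetry and categorical land-cover rasters — and it ships with a
synthetic-landscape generator with known generative truth, so every stage
can be validated end to end without any data download.

## The models

**Population level.** Presences vs. pseudo-absences (4:1, background
drawn outside a 5,600 m exclusion buffer — the radius of a circle with
the 99.7 km² mean home-range area) in a logistic regression on
moving-window land-cover proportions (square windows of 7–50 km², edge
√area) and distance covariates. Candidate models are ranked by

    AICc = −2LL + 2k + 2k(k+1)/(n−k−1),

Akaike weights w ∝ exp(−Δ/2), and models within ΔAICc ≤ 2 are averaged on
the probability scale into a suitability surface H ∈ [0, 1].

**Individual level.** 95% isopleths of Gaussian KDE home ranges
(reference bandwidth), equal-count uniform availability within each
isopleth, and a distribution-weighted exponential resource selection
function w(x) = exp(βᵀx) in which every animal carries equal total weight;
the exponential RSF and the logistic RSPF alternative are compared by
CAIC = −2LL + k(ln n + 1).

**Connectivity.** Suitability becomes resistance R ∈ [1, 100] via a linear
rule or the exponential-decay family R = 100 − 99(1−e^(−cH))/(1−e^(−c))
(c ∈ {2, 8}). The raster is a resistor network (8-neighborhood,
average-conductance edges, diagonals ÷ √2); node regions are contracted
and pairwise unit currents solved from the graph Laplacian, giving current
density (corridors), effective resistances (isolation), and decile maps.
Candidate maps are validated against disperser locations with matched
random points via a random-intercept logistic model (adaptive
Gauss–Hermite marginal likelihood, cross-checked against `lme4`), and
averaged with AICc weights.

## Worked example

`examples/` contains one short script per capability. The first builds a
6 × 6 km synthetic landscape, draws 1,000 presences from a known logistic
selection surface, and refits:

```bash
python examples/01_population_rsf.py
```

```text
use-availability rows: 6239 (1000 presences)

model selection table (best first):
                                       model  k  log_likelihood     aicc  delta_aicc  weight
forest_7km2 + pasture_7km2 + dist_main_roads  4       -2538.975 5085.956       0.000   1.000
               forest_7km2 + dist_main_roads  3       -2582.072 5170.148      84.193   0.000
                                 forest_7km2  2       -2602.533 5209.069     123.113   0.000
                                        null  1       -2746.017 5494.035     408.079   0.000

recovered coefficients (truth in parentheses):
  forest_7km2      +1.020  [+0.905, +1.135]  (true +1.0)
  pasture_7km2     +0.522  [+0.412, +0.632]  (true +0.5)
  dist_main_roads  -0.341  [-0.421, -0.261]  (true -0.3)

AUC ROC of the top model: 0.697
model-averaged suitability: mean 0.161, range 0.014-0.436
```

The generative model (forest +1.0, pasture +0.5, distance to main roads
−0.3 on scaled covariates) wins the AICc ranking outright, and every 95%
confidence interval covers its true coefficient. The other examples walk
through home ranges and the weighted RSF (`02`), pairwise current flow and
decile corridors (`03`), disperser-based map validation (`04`), and the
seeded end-to-end pipeline (`05`).

The pipeline is also scriptable from the shell:

```bash
habconn run-all --seed 11 --outdir run1      # byte-reproducible artifacts
habconn connect --config my_config.yaml      # just one stage (+ deps)
```

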