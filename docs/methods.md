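# Methods

`habconn` implements a two-level habitat-selection analysis and a
circuit-theory connectivity analysis for a recolonizing carnivore
population, exercised end to end on synthetic landscapes with known
generative truth. This note records the models, the parameters that
matter, the numerical choices, and what the synthetic data do and do not
demonstrate.

## Population-level resource selection

Verified occurrence records are contrasted against pseudo-absences in a
use–availability logistic regression. Pseudo-absences are drawn uniformly
over the study extent but outside an exclusion buffer around every
presence; the buffer radius is that of a circle whose area equals the mean
home range (99.7 km² → 5,633 m, rounded to 5,600 m), so that background
points are plausibly outside occupied ranges. The availability ratio is
4 pseudo-absences per presence.

Covariates are land-cover proportions in square moving windows whose edge
is √area — 7, 15, 30 and 50 km² windows have edges of 2.65, 3.87, 5.48 and
7.07 km — rounded to an odd cell count so the window centers on its focal
cell (89 cells for 7 km² on a 30 m raster). Windows are truncated at the
grid boundary and proportions are taken over the available (non-nodata)
cells, which avoids edge inflation. Distance surfaces are exact Euclidean
distance transforms from rasterized line features; road density is
kilometers of road per km² in the same square windows, with per-cell road
lengths computed by exact segment/cell-box clipping. All covariates are
centered and scaled to SD 1 over valid cells before modeling, and the
training means/SDs are retained so points and held-out data receive the
identical transform. Covariate pairs with Pearson |r| > 0.7 are flagged
for removal before model building.

Candidate models never contain the same land-cover variable at two scales
(the scales are strongly collinear). Models are ranked by
AICc = −2LL + 2k + 2k(k+1)/(n−k−1) with n = the number of rows in the
use–availability table (presences + pseudo-absences; the choice of n for
AICc is a convention — at these n the small-sample term is far below the
printed precision). Akaike weights are exp(−Δ/2) renormalized. Models
within 2 AICc units of the best are averaged on the probability scale with
renormalized weights, giving the suitability surface H ∈ [0, 1].
Discrimination is summarized by the rank-statistic (Mann–Whitney) AUC with
tie correction, and predictive ability by repeated 95/5 split-sample
classification accuracy at threshold 0.5 (the threshold and metric are a
package convention; a single "accuracy" is not otherwise well defined).

### Parameter recovery and the generative design

Two presence generators are provided. `generate_presences` samples
presence *cells* with probability proportional to expit(β₀ + βᵀx) — the
right tool for making maps and sign checks. For confidence-interval
*coverage* checks the package uses `generate_use_availability`, which
draws candidate cells uniformly and labels them Bernoulli(expit(β₀ + βᵀx)):
under this design the logistic refit is exactly correctly specified, so
nominal 95% coverage is the mathematically expected outcome and deviations
indicate implementation error. Contrasting presences sampled ∝ expit
against *fresh* uniform background is a subtly misspecified logistic
problem (the contamination bias of use–availability designs) and would
conflate that bias with software defects.

## Individual-level (home-range) selection

Animals with ≤ 30 fixes, or flagged as dispersers, are removed. Each
remaining animal's utilization distribution is a product-Gaussian KDE with
the per-axis reference bandwidth h_i = σ̂_i · n^(−1/6), evaluated on a
local grid extending 4 bandwidths beyond the fixes at ≥ 200 cells per
axis; the home range is the smallest set of cells holding 95% of the
density mass (mass renormalized to the local grid, so truncation cannot
shrink the isopleth), and its area is the cell count × cell area. The
bandwidth rule is the deterministic ecology default; no plug-in or
cross-validated bandwidth is attempted.

Availability is sampled uniformly within each animal's isopleth, one
available point per fix. Selection is estimated from the use–availability
logistic likelihood with per-observation weights; under the
*distribution-weighted* scheme each observation of animal i has weight
N_total/(I·n_i), so every animal contributes equal total weight no matter
how well its collar performed. The exponential RSF scores relative
selection w(x) = exp(βᵀx) (intercept absorbed by the sampling ratio); the
logistic RSPF reports bounded selection probabilities. The two forms are
compared by consistent AIC, CAIC = −2LL + k(ln n + 1), with n = the number
of used + available rows. Use-probability curves are the fitted scores at
*available* points plotted against one covariate with a lowess smooth
(span 0.75, one robustness iteration); they describe probability of use
under the current availability of the other covariates and change when
that availability changes.

Group contrasts of home-range area (by sex, by study area) use the
Kruskal–Wallis rank test with tie correction against a χ² reference.

## Connectivity

Suitability is mapped to resistance on a fixed [1, 100] scale, either
linearly, R = 100 − 99H, or with the exponential-decay family

    R = 100 − 99·(1 − e^(−cH)) / (1 − e^(−c)),

where c = 2 gives an intermediate shape and c = 8 lets resistance fall
sharply at low suitability. The linear rule is mapped onto the same
[1, 100] range so the three maps are comparable before averaging.

The raster is a resistor network: one node per valid cell, 8-neighborhood
edges with conductance equal to the arithmetic mean of the two cells'
conductances (1/R), diagonal edges scaled by 1/√2 — the standard
average-conductance convention for conductance surfaces. Node regions are
contracted to super-nodes (parallel edges merge additively; internal edges
vanish). For each unordered region pair, unit current enters one region
and the other is grounded; node potentials solve the reduced graph
Laplacian by sparse LU on the connected component containing the pair
(a disconnected pair is an explicit error naming the components). Per-cell
current density is half the sum of absolute incident edge currents;
source/ground cells instead carry the full current they feed into the
network, so the map shows what each terminal cell contributes. Effective
resistance is the potential difference per unit current. The cumulative
map sums the per-cell current over all pairs (10 pairs for 5 regions) and
is classified into 10 equal-count bins over the valid cells with *positive*
current (zero-current cells are left in bin 0; computing quantiles over
positive cells keeps the bins informative when much of the map carries no
flow).

## Disperser-based validation

Candidate disperser locations ("used", 1) are each matched with 3 random
points ("available", 0) uniform in a disc around the location (5,000 m in
the full-scale configuration; desk-scale runs shrink the disc with the
landscape). Every point is scored with the decile of each candidate
connectivity map. Each map is then evaluated by a random-intercept
logistic regression of used/available on decile with location as the
grouping factor, k = 3 (intercept, slope, random-intercept SD).

The marginal likelihood integrates the scalar random effect per location
with *mode-centered adaptive Gauss–Hermite quadrature*: a Newton step
(globally convergent — the integrand is log-concave) finds each location's
conditional mode and curvature, and a 7-node rule integrates around it;
one node reduces exactly to the Laplace approximation, and the test suite
requires Laplace and 7-node marginal log-likelihoods to agree within 0.05
on matched-set-shaped fixtures. The optimizer is Nelder–Mead over
(intercept, slope, log σ). The implementation is validated against
`lme4::glmer` (nAGQ = 7) in an R-oracle test: slope and marginal LL agree
to 10⁻³.

AICc over the (usually three) map models yields Akaike weights; the final
connectivity map is the weighted average of the candidate maps after each
is normalized to unit mean over valid cells. Raw current maps from
different resistance shapes have incomparable scales, so some
normalization is required before averaging; unit-mean normalization is the
package's choice and is recorded here because no canonical convention
exists.

## Synthetic data: what it emulates and what it does not

The generator produces (i) a categorical land-cover mosaic by thresholding
a smoothed Gaussian random field at quantiles matching the target class
proportions — patchy, spatially autocorrelated, seed-reproducible; (ii)
road and stream polylines crossing the extent with lateral jitter, in two
traffic classes; (iii) presences from a known logistic selection surface;
(iv) per-individual telemetry from bivariate-normal home-range kernels
thinned by exp(βᵀx), with configurable fix counts (31–630 by default,
emulating variable collar performance); (v) dispersers sampled with
probability ∝ current^preference (preference 0 = uniform).

Default study conditions mirror the analysis constants: 4:1 availability,
{7, 15, 30, 50} km² windows, |r| > 0.7 screen, ΔAICc cutoff 2, 95%
isopleth, > 30-fix filter, transforms {linear, c = 2, c = 8}, 5 node
regions, 10 deciles, 46 dispersers with 3 available points each. The
default synthetic extent is 200 × 200 cells at 30 m (6 × 6 km); this is a
desk-scale landscape, so lengths tied to the full-scale study are scaled
with it (the pseudo-absence exclusion buffer shrinks when it would leave
no free background area, and validation discs use 600 m on 3 km maps).
Problem sizes used by the test suite — 200 × 200 landscapes with 1,000
presences × 200 replicates for coverage, 20 animals × 60 fixes × 100
simulations for sign recovery, 100 × 100 maps × 100 replicates for the
validation stage — were chosen as the smallest sizes at which the checked
statistical properties are stable.

What passing tests show: the estimators are correctly implemented (closed
forms, independent oracles, nominal coverage under the matched generative
design), the circuit solver is exact to solver tolerance, and the full
pipeline is deterministic under a fixed seed. What they do not show:
robustness to real-data pathologies — observer effort bias in citizen
sightings, GPS fix-rate habitat bias, temporally autocorrelated fixes
(the KDE assumes exchangeable fixes; an autocorrelation-adjusted home
range would differ), non-Gaussian home-range shapes, or map error in the
land-cover product.

Within-home-range coefficient magnitudes are attenuated relative to the
generative thinning strength because availability is drawn from home
ranges that are themselves placed by the kernels, and fixes concentrate
near kernel centers; sign recovery, not magnitude recovery, is the tested
property at the individual level (the population level recovers
magnitudes).

## Numerical choices and degenerate inputs

* Window edge: odd cell count nearest √area/cell_size; windows below one
  cell are errors.
* Distance transforms: center-to-center exact Euclidean
  (`scipy.ndimage.distance_transform_edt`); an empty source set is an
  error, not an all-infinite grid.
* Logistic fits: IRLS via `statsmodels` GLM; rank-deficient designs and
  (quasi-)perfect separation raise named errors.
* KDE: product Gaussian evaluated as a matrix product (grid × fixes);
  all-identical fixes raise a bandwidth error; a single fix is allowed
  only with an explicit bandwidth.
* Circuit solve: sparse LU (`splu`) on the grounded Laplacian; mirror
  symmetry holds to 1e-8; effective resistance matches a dense
  pseudoinverse oracle to 1e-8 (the oracle itself needs `rcond ≈ 1e-13` —
  default singular-value truncation discards genuine small eigenvalues of
  ill-conditioned Laplacians).
* Quantile bins: `side="left"` tie-break sends values equal to a bin edge
  upward; fewer distinct positive values than bins is an error.
* GLMM: 50-iteration Newton cap for conditional modes (tolerance 1e-10);
  Nelder–Mead with xatol 1e-7/fatol 1e-9; decile columns without variation
  and single-location data are errors.
* Master seed → per-stage seeds via `numpy.random.SeedSequence.spawn`, so
  stages are independently reproducible and the whole pipeline is
  byte-deterministic (fixed text formats for all artifacts).

## Known limitations

* ESRI ASCII is the only raster format (single band, square cells);
  vector I/O is CSV/GeoJSON. No reprojection — all inputs must share a
  projected metric CRS.
* The moving window is square (edge √area). Circular windows of equal
  area would differ slightly at window corners.
* The exponential-RSF and logistic-RSPF fits share the weighted
  use–availability likelihood; they differ in the reported scale, not in
  the estimation route.
* The GLMM supports one scalar random intercept and one fixed covariate —
  exactly the validation design — not a general mixed-model interface.
* Pairwise current flow only; all-to-one and advanced modes of
  circuit-theory packages are out of scope, as is treating roads as
  explicit barriers.
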