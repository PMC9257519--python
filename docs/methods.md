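# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `rangeshift`, in the order the pipeline runs them.

## Grid and raster model

All computation happens on a planar equal-area grid of square cells
(default side √9.2 ≈ 3.033 km, i.e. 9.2 km² per cell, matching the native
resolution of the oceanographic products the pipeline is designed
around). Coordinates are kilometres; indexing is 0-based row-major from
the lower-left corner with half-open cell intervals; missing cells are
NaN. Continuous layers are regridded by bilinear interpolation of the
four surrounding source cell centers (exact on planes, bounded by the
contributing values); categorical layers by nearest neighbour, since
interpolating class codes is meaningless. Reprojection between coordinate
reference systems is out of scope: every area and distance in the
pipeline is a planar Euclidean quantity, so an equal-area projection is
assumed upstream. Rasters are serialized as ESRI ASCII grids — a text
format that diffs cleanly and that GDAL/QGIS read natively.

## Synthetic study system

The generator emulates a brackish shelf sea, not any specific dataset:

- **Spatial autocorrelation** comes from Gaussian-smoothing white noise
  (kernel default 4 cells) and rescaling to the target range. This gives
  smooth, seeded, cheap fields; it does not reproduce anisotropy,
  coastline-driven structure, or realistic variograms.
- **Salinity** is a linear north→south gradient (defaults 25 PSU at the
  northern edge to 7 PSU at the southern edge) plus ±1 PSU smoothed
  noise — the dominant environmental axis of the target system.
- **Bathymetry** spans −5 to −80 m; **slope** is its gradient magnitude
  in degrees; **sediment** is a 5-class factor from quantile bins of an
  independent smooth field; **temperature** is 8 ± 3.5 °C and **current**
  0.15 ± 0.10 m/s (smoothed noise). The temperature amplitude matters:
  it sets how much of a +2.7 °C future remains within the training
  envelope, i.e. how much of the map survives novelty masking. A ~7 °C
  spatial spread is typical of an annual-mean basin gradient at this
  extent.
- A common land mask (default 5% of cells) is carved where an
  independent smooth field is highest, and propagates through every
  layer.
- **Species truth** is `suitability = logistic(η)` with η an intercept
  plus linear/quadratic terms on min-max-scaled covariates and optional
  categorical offsets — deliberately inside the fitted model family so
  structure recovery is well-posed. The fitted cloglog output is *not*
  expected to equal this truth numerically; all downstream claims are
  rank-based (AUC, thresholds), not calibration-based.
- **Presences** are drawn per cell with probability ∝ suitability ×
  sampling bias, then placed uniformly within the cell. The demo's bias
  truth is a Gaussian effort hub (σ = 25% of the domain width) centered
  west of the domain middle — the confound the bias-correction stage
  must undo.
- **Haulouts** get uniform elevations on 0–1.2 m, straddling every
  scenario flooding cutoff (0.24–0.75 m), with regions assigned by
  north-south terciles.
- **Tracks** are GPS-like: positional error, duty cycles and movement
  autocorrelation are not simulated. Preprocessing drops the first 24 h
  after deployment and keeps, per date and target hour (03/09/15/21),
  the fix nearest the target, ties to the earlier fix; Argos-type tracks
  pass through the 24-h cut unchanged.

Passing tests on this system demonstrates the pipeline's internal
correctness and its ability to recover known structure under controlled
bias; it does not demonstrate fidelity to any real population.

## Scenario covariates

Future water level is `mean sea-level rise + regional isostatic offset`
(defaults 0.39/0.65 m for the moderate/severe scenario; +0.10 m
southwestern Baltic, −0.05 m southern Kattegat/Bornholm, −0.15 m
central-northern Kattegat). The current period is the zero baseline by
definition. A haulout floods when its elevation does not exceed the
effective rise — the tie goes to flooding, a conservative choice. The
distance-to-nearest-haulout covariate (seal-like species only) is planar
Euclidean from each cell center to the nearest surviving site,
recomputed per scenario; distances cross land freely (no least-cost
paths), a documented simplification. No new haulouts can emerge.

Collinearity is reported, never acted on: VIF per continuous variable
(ordinary least squares of each on the others at the presence +
background locations; infinite for perfect collinearity) and pairwise
Spearman correlations. The categorical sediment factor is excluded from
both.

## Sampling-bias correction

The bias surface is an isotropic Gaussian kernel density of the
occurrence locations evaluated at cell centers, masked and renormalized;
background points (default 10,000) are drawn with replacement ∝ bias and
jittered within cells. The `bias_surface` operation defaults to Scott's
rule for the bandwidth, but the pipeline overrides it with an
effort-scale bandwidth (default 40 km): a density-optimal bandwidth on
the occurrences under-smooths, reproducing the *biological* density
rather than the sampling effort, which cancels the signal the model is
supposed to learn. The 40 km default reflects the spatial scale of
tagging-effort aggregation (deployment hubs), and is configurable. One
background set is drawn per species and reused across all tuning
candidates. Presence cells are not excluded from the background.

## Maximum-entropy fit

Features: continuous variables are scaled to [0,1] by the background
min/max (prediction-time values clamped; genuine novelty is handled by
MESS, not clamping), then expanded per feature class L/Q/LQ; categorical
variables contribute one-hot indicators, with unseen prediction-time
levels yielding all-zero indicators plus a warning (the pipeline
additionally masks such cells). Hinge/product/threshold features are
deliberately unsupported.

Penalties: `β_j = RM · τ(class, m) · sqrt(max(v_j, 10⁻⁴) / m)` with τ
interpolated log-linearly in the presence count m from the tables
{m=10: 1.0, m=30: 0.2, m≥100: 0.05} (continuous features) and
{m=10: 0.25, m≥17: 0.05} (categorical indicators), clamped at the
endpoints. These follow the published defaults of the reference
implementation in spirit and are configuration-exposed, not claimed as
exact.

Solver: FISTA with backtracking line search, soft-threshold proximal
step, gradient-based adaptive restart, and a step-size relaxation each
iteration. Convergence is declared when the maximum violation of the L1
KKT stationarity conditions falls below `tol` (default 10⁻⁸ for library
calls; the pipeline uses 10⁻⁶, which changes coefficients well below any
reported digit). Non-convergence returns the best iterate, flagged. The
empty feature set yields the exact uniform distribution. Tests verify
the fit against an independent convex minimizer (L-BFGS-B on the
split-sign reformulation) to |Δλ| < 10⁻³ and ΔJ < 10⁻⁸ on random small
landscapes.

## Tuning and selection

Random k-fold partition of presences (default k = 5; the background is
shared across folds). Per fold and candidate: fit on training presences,
score with raw output, record presence-vs-background AUC (Mann–Whitney
with tie correction) and OR10. The OR10 training threshold is the
(⌊0.1 m⌋+1)-th smallest training score with strict `<` counting, so
train-as-test omission is exactly ⌊0.1 m⌋/m. A consequence worth knowing:
the *expected* test omission is (⌊0.1 m⌋+1)/(m+1), slightly above 0.10,
so the OR10 < 0.10 eligibility filter is strict and the min-OR10 fallback
is not rare. Selection is two-step — filter to mean OR10 < 0.10, then
maximize mean AUC, ties to lower RM then the simpler class — with the
min-OR10 fallback logged when no candidate passes. The selected
configuration is refit on all presences. Raw scores are used for the
metrics: AUC is transform-invariant, and fixing the scale makes OR10
thresholds reproducible.

## Projection and novelty masking

MESS is computed per continuous variable against the presence locations'
current-condition values (not the background), with the standard
piecewise percent-scale similarity; the per-cell score is the minimum
over variables and the arg-min variable is recorded. `f`, the fraction of
reference values below the cell value, uses strict `<`. Cells with
negative similarity — at least one variable outside its reference range —
are masked from projection, as are cells with a sediment class unseen at
the presence locations. Degenerate references (max = min) contribute 0
at the reference value and −∞ elsewhere.

## Change metrics

Thresholds are computed once from the final model's cloglog scores at the
presence and background points (background standing in for absences, as
with AUC) and applied unchanged to all periods. Candidate cutoffs are the
unique observed scores; ties resolve to the smallest cutoff; binarization
is `suitability ≥ t`. Area is cell count × 9.2 km². The Clark–Evans NNI
uses suitable-cell centers, with the expected nearest-neighbour distance
`1/(2√ρ)` under complete spatial randomness at density ρ = n / (valid
non-novel area of that period's projection); no Donnelly edge correction
is applied (the uncorrected index is biased slightly upward near edges,
visible as CSR simulations averaging just above 1). Overlap is the
cellwise AND across species' binary maps for every pairwise and the
all-species combination, with missing cells propagating.

## Pipeline and reproducibility

One seed drives everything through `numpy.random.SeedSequence` substreams
(environment, haulouts, and per species: presences, background, folds),
so runs are byte-identical per config + seed and removing one species
does not perturb another's outputs. Configuration is YAML validated by
pydantic models; the scenario constants, background size, RM grid and
fold count are defaults, not hard-coded. The bundled demo uses a 60×60
grid, two species of 300 presences each, 10,000 background points and
the full 30-candidate grid — sized to finish in a few minutes on one
CPU; the structure-recovery experiment in the tests uses 40×40 grids,
200 presences and 1,500 background points per replicate for the same
reason. That experiment cross-validates with k = 6 folds rather than the
pipeline's default 5: with 200 presences, 5-fold training sets have
exactly 160 members, putting 0.1·m on an integer — the point where the
omission-threshold order statistic is most upward-biased and the
OR10 < 0.10 eligibility filter degenerates into its fallback. Training
folds of 166–167 avoid that. Even so, the omission filter mildly favours
the simpler feature classes (flexible models omit slightly more test
presences), so class recovery is a majority outcome, not a certainty.

## Known limitations

- Planar Euclidean geometry throughout; no CRS handling, no over-water
  distances.
- Presence-background AUC under strong bias correction is conservative
  (background resembles presences by design), so demo AUCs undershoot
  what uncorrected sampling would suggest.
- The synthetic system has no temporal dimension: "periods" differ only
  by additive deltas and haulout loss.
- NNI is computed without edge correction and on cell centers, so very
  small suitable sets quantize coarsely.
- The original Java MaxEnt's clamping modes, hinge features and logistic
  output are intentionally absent; numerical equality with that software
  is not a goal — distributional and rank properties are.
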