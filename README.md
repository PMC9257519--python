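# rangeshift

Habitat-suitability and range-shift forecasting for presence-only wildlife
data. `rangeshift` fits presence-background maximum-entropy (MaxEnt-style)
species distribution models to tracking-derived occurrence points, tunes
them by cross-validated omission rate and AUC, projects them onto current
and future climate-scenario rasters with novel-condition masking, and
quantifies how suitable range area, its spatial clustering, and
inter-specific overlap change between periods. It is aimed at spatial
ecologists studying marine mammals (or any presence-only system) on a
planar equal-area grid — the motivating setting is seals and porpoises in
a brackish shelf sea under sea-level rise and warming/salinification
scenarios.

Because real telemetry and oceanographic data are rarely shippable, the
package includes a first-class synthetic-data module that generates
spatially autocorrelated environment rasters (bathymetry, seabed slope, a
5-class sediment factor, current, temperature, and a north-to-south
salinity gradient), scenario futures, haulout sites with elevations, and
presence points drawn from known linear + quadratic response surfaces with
spatial sampling bias — so every stage of the pipeline is testable against
a known truth.

## The model

Given presence feature vectors `f(x_1) … f(x_m)` and a background sample
of size `N`, the model is the Gibbs distribution over the background that
minimizes the penalized negative log-likelihood

```
J(λ) = −(1/m) Σ_i λ·f(x_i) + log Z(λ) + Σ_j β_j |λ_j|,
Z(λ) = Σ_background exp(λ·f(x))
```

Features are linear and/or quadratic transforms of min-max-scaled
covariates plus one-hot sediment indicators (feature classes L, Q, LQ);
the per-feature L1 penalties `β_j = RM · τ(m) · sqrt(v_j/m)` follow the
classic sample-size-dependent defaults, all scaled by a regularization
multiplier RM. The fit is an accelerated proximal-gradient (FISTA) solve
with a KKT stopping rule. "Raw" output is the fitted probability
`p(x) = e^{λ·f(x)}/Z` (sums to 1 over the background); the mapped
suitability index is the complementary log-log transform
`1 − exp(−e^H p(x))` with `H` the entropy of the raw distribution.

Model selection evaluates RM ∈ {0.5, …, 5.0} × {L, Q, LQ} (30 candidates)
by k-fold cross-validation: candidates with mean 10% training omission
rate (OR10) below 0.10 are kept and the highest test AUC among them wins.
Projection masks cells whose multivariate environmental similarity (MESS)
to the presence-location conditions is negative, i.e. truly novel
climates. Suitability maps are binarized at three thresholds — maximum
Cohen's kappa, maximum sensitivity + specificity (MSSS), and the 10%
presence percentile (P10) — and summarized as area (km²), Clark–Evans
nearest-neighbour index (NNI < 1 clustered, > 1 dispersed), and cellwise
inter-specific overlap.

## Worked example

The bundled demo (60×60 grid of 9.2 km² cells, two synthetic species,
current + RCP6.0 + RCP8.5 scenarios) runs in a couple of minutes:

```
python analysis/01_generate_data.py     # synthetic environment + haulouts
python analysis/02_tune_models.py       # per-species tuning and selection
python analysis/03_project_scenarios.py # MESS-masked projections
python analysis/04_change_and_overlap.py
```

or equivalently `rangeshift run --outdir results/pipeline` (see
`examples/demo.yaml` for the config). Step 01 prints, for seed 0:

```
salinity: north row mean 25.2 PSU -> south row mean 6.8 PSU
sediment classes: [1, 2, 3, 4, 5]
haulouts: 25 sites, elevations 0.10-1.20 m (flooding cutoffs span 0.24-0.75 m)
```

The `seal_like` species is built with a negative linear salinity response
and haulout-distance decay; `porpoise_like` with a concave quadratic
salinity response. Step 02 reports the selected configurations and the
three binarization thresholds per species (e.g. seal: kappa 0.783, MSSS
0.575, P10 0.391 — kappa most restrictive, P10 most inclusive). Step 04
prints the headline tables; at seed 0 the salinity-averse seal loses
suitable area in every scenario × threshold combination (net −34,813 km²
summed over all of them) while the porpoise's mid-salinity optimum shifts
but roughly holds (net +892 km²), and the species' shared suitable area
declines with scenario severity at the inclusive thresholds:

```
            combination  period threshold  area_km2
seal_like+porpoise_like current      msss    3192.4
seal_like+porpoise_like  RCP6.0      msss    1858.4
seal_like+porpoise_like  RCP8.5      msss    1067.2
```

At the restrictive kappa threshold the overlap first shrinks (101 → 92
km²) and then rises (156 km²) under the severe scenario as both compressed
ranges collapse onto the same mid-domain refugium — a behaviour real
multi-species forecasts also show.

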