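# ecostab

**ecostab** assesses the ecological stability of a region from the
persistence of its landscapes. It is aimed at landscape ecologists and
geospatial analysts who have a multi-date categorical land-cover series and
a set of environmental covariate rasters, and who want a spatially explicit,
probability-based stability surface rather than an ad-hoc index — especially
for large, data-sparse regions where direct ecosystem measurements are not
available.

## The model

A landscape pixel is *steady* when its land-cover class is unchanged over
every observation date, and *unsteady* when it holds the class at the first
date but changes later. Within each landscape type the probability of being
steady is modelled as a logistic function of min–max-normalized
environmental factors `Z_i = (X_i − X_min)/(X_max − X_min)`:

    log( P / (1 − P) ) = β₀ + β₁Z₁ + β₂Z₂ + ⋯ + βₙZₙ

fitted per landscape by maximum likelihood. The fitted probability surface
is the **Ecological Stability Index** of that landscape,

    ESIᵢ = Pᵢ = e^(β₀+β₁Z₁+⋯+βₙZₙ) / (1 + e^(β₀+β₁Z₁+⋯+βₙZₙ)) ∈ [0, 1],

and the regional surface is their **Maximum Value Composite**,

    ESI = max{ ESI₁, ESI₂, …, ESIₙ },

averaged over years and classified into five levels (very low [0, 0.2) …
very high [0.8, 1]). Per-pixel linear regression of annual ESI on calendar
year, with a two-sided t-test on the slope, gives the trend map. The index
is validated by its Pearson correlation with vegetation greenness (EVI) and
by the contrast between protected and unprotected areas. Coefficients on
the normalized scale are directly comparable across factors and serve as
per-factor contributions to stability.

The pipeline stages are: persistence labelling of each ecological
land-cover class (forest, grassland, wetland; desert and urban are
excluded) → demotion of steady pixels with erratic NDVI/GPP (treated as
classification error) → k-means landscape typing on vegetation features
(grassland splits into sparse vs. high-coverage) → per-landscape,
per-year logistic fits → ESI surfaces → composite, classes, trend,
validation. A seeded synthetic-scene generator with known ground truth
makes every stage testable end to end.

## Worked example

Generate the demo scene and run the pipeline:

```bash
ecostab simulate --outdir demo/scene --seed 42 --rows 100 --cols 100
cat > demo/config.yaml <<'YAML'
scene_dir: demo/scene
outdir: demo/out
seed: 42
YAML
ecostab run --config demo/config.yaml
```

which reports `16 models fitted; outputs in demo/out` (4 landscapes ×
4 years). The manifest (`demo/out/manifest.json`) shows, for this seed:

* persistence: e.g. forest 1287 steady / 213 unsteady pixels; typing finds
  four landscapes (forest 1500, sparse grassland 3296, high-coverage
  grassland 2203, wetland 1000 eligible pixels);
* stability-class shares of the mean composite: medium 25.8 %, moderately
  high 54.0 %, very high 20.2 %;
* trend at α = 0.05: 1.5 % of pixels significantly increasing, 1.0 %
  decreasing;
* validation: ESI–EVI Pearson r = 0.68 (p ≈ 0, n = 7999); mean ESI 0.751
  inside the reserve vs. 0.676 outside.

`demo/out/models/contributions.csv` ranks the drivers per landscape and
year; for the forest model of the first year the strongest contribution is
temperature (coefficient +1.84 on the normalized scale), matching the
coefficient planted by the generator (+1.5) within its standard error.
Because every ESI is a probability, a value of e.g. 0.75 reads directly as
"three-to-one odds that this landscape keeps its ecosystem type under these
environmental conditions".

The same stages are available as library functions
(`ecostab.compute_persistence`, `ecostab.fit_logistic`,
`ecostab.predict_esi`, `ecostab.mvc_composite`, …) and as stage
subcommands (`ecostab persist|type|fit|map|composite|trend|validate`).

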