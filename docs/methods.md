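# Methods

## Scope and model structure

The package estimates how many carbon credits an HFLD territory could claim
under alternative reference levels. Seven baseline families produce
cumulative deforestation 2015–2050; one spatial model places that
deforestation on the landscape; a final arithmetic layer converts the gap
between a candidate baseline and the historical pathway into tCO₂e, money
and GDP shares. Every model carries a multiplicative error: `logN(m; σ)`
denotes a log-normal whose *natural-log median* is `m` with log-scale SD σ.
This choice reflects that deforestation errors scale with the predicted
amount; it also makes the mean `exp(m + σ²/2)` strictly above the median,
which matters when envelopes are wide.

### Time indexing

Projection uses 35 annual increments (2015 is the first cleared year).
Cumulative totals are labelled with the year each increment completes,
2016–2050, so the terminal entry is the 2050 total and the ERB identity
"available area / 35 per year ⇒ everything by 2050" holds exactly. This
resolves an off-by-one ambiguity between "years 2015–2050" (36 labels) and
the division by 35.

### Calibration

* **HA** — `Def^HA = log(arithmetic mean of annual loss 2001–2014)`; σ is
  the sample SD (ddof = 1) of the log of the positive annual values. Years
  with zero observed loss contribute to the mean but not to σ (their log is
  undefined); at least two positive years are required. This σ is injected
  unchanged into all normative trajectories (ERB, JRC, CI), which have no
  error model of their own.
* **GM** — per territory, OLS of log gold-mining deforestation on log gold
  price gives the intercept and price elasticity θ^V; σ^GM is the pooled
  residual SD with 2 dof per territory removed. A pooled cross-territory
  OLS of log non-gold deforestation on log PopCh (mean annual population
  change, persons/yr, constant over the projection) gives the demographic
  coefficients. With a single territory the demographic slope is
  unidentified and the fit degrades to intercept-only. A constant gold
  price raises a calibration error rather than returning a spurious
  elasticity. Historical loss is split into gold / non-gold components by
  proximity to greenstone (default 10 km; the bundled synthetic landscape
  is only ~9 km across, so its config uses 1.5 km).

### Projection choices

* JRC and CI recursions update forest cover with the *median* annual
  deforestation; these are normative, deterministic-centre scenarios whose
  uncertainty enters only through the shared σ. The JRC rate is floored at
  zero (no negative deforestation, no debt).
* The printed JRC constants are internally tense: half of 0.52 %/yr
  decreasing by 0.0029 points/yr crosses zero ~90 years after the start,
  i.e. near 2100, not 2050. The defaults keep the printed α = 0.0029;
  `JRCParams.from_zero_year` instead derives α = (WDR₀/2)/(zero_year − 2011),
  which reproduces 0.0029 for a 2100 target and is what the pipeline's
  JRC2050/JRC2100 scenarios use. Similarly 0.275 %/yr is kept as printed
  even though half of 0.52 is 0.26; both are independently configurable.
* GM cumulative uncertainty has no closed form (a sum of log-normals), so
  it is summarized by Monte Carlo: mean and 2.5/97.5 percentiles over
  10,000 seeded draws by default. Analytic trajectories use
  `exp(μ ± 1.96σ)` envelopes; both conventions are available.

### Spatial allocation

The location model is a random forest (500 trees, √p candidate covariates
per split, minimum leaf 5; the demo and recovery analyses use 100–200 trees,
which leaves the importance ranking unchanged) over six static covariates:
protected-area indicator and Euclidean distances (m) to roads, greenstone
belts and three Strahler stream classes (1–3, 4–6, 7+). Training positives
are pixels lost 2001–2014 inside the 2000 forest mask; the background is a
seeded 1:1 random sample of never-lost forest. Importance is the Gini
impurity decrease (MDG); an empty feature class yields a sentinel distance
and zero importance. Intensity coupling draws exactly
`round(area / 0.09 ha)` pixels per year without replacement, probability
proportional to risk, via Gumbel-key sampling (reproducible under a seed,
and exact for the weighted-without-replacement law). ERB allocation masks
protected pixels outright rather than re-normalizing afterwards; other
scenarios let the protected indicator act as an ordinary covariate.
Demand beyond the remaining pool is capped with a warning.

### Crediting

Avoided area = max(0, scenario − historical) *mean* cumulative at 2050 —
the log-normal mean, consistent with plotting conventions — with bounds
from the scenario envelope only (the historical path is treated as what the
territory actually does). Carbon: 265 t/ha dry aboveground biomass × 0.5
carbon fraction = 132.5 tC/ha, × 44/12 → tCO₂e; prices 5 and 30 USD/tCO₂e;
shares against mean yearly GDP 2001–2014 (cumulated credits vs one year's
GDP, so shares may exceed 100 %). The payment fraction between the
full-payment (0.056 %/yr) and no-payment (0.1 %/yr) rates is linear — only
the endpoints are specified by the rule, and linearity is the minimal
interpolation. Belowground biomass, soil carbon and degradation are
excluded.

## Synthetic data

The generator emulates everything the real analysis takes from global
forest-change rasters, GIS layers and statistics offices, on a small
north-up grid (30 m pixels, 0.09 ha):

* tree-cover % as a smooth random field around 88 % (dense rainforest);
* roads as transecting polylines; greenstone belts as blobs stratified
  across the grid width (belts traverse the region, so no large
  sub-territory is void of them); protected areas and coastal swamps as
  disk unions grown to a target fraction;
* a drainage network as a random spanning tree with Strahler orders
  computed bottom-up — this yields the three stream distance classes
  without hydrological modelling (high orders, 7+, may be absent on small
  grids, in which case the distance layer is a flagged sentinel);
* loss histories placed by weighted sampling without replacement from a
  planted logistic risk surface (log-odds linear in z-scored covariates
  plus noise), so the downstream model family can recover the planted
  weights. An optional patch-growth mode (`patch_px`, `min_patch_px`)
  clusters loss into connected clearings of geometric size; real
  deforestation is patchy, and without it sparse HFLD-scale histories are
  erased by the isolated-pixel filter. Per-year pixel counts are exact to
  one pixel in all modes;
* gold price defaults to a deterministic 2001–2014 path peaking at
  1538.5 USD/oz (so the doubled-maximum rule gives 3077), population and
  GDP as linear/geometric growth, and GM-model deforestation series as the
  sum of the two log-normal components — used for parameter-recovery tests.

What the generator does *not* emulate: real geomorphology, road-network
topology, spatial autocorrelation of land tenure, forest-cover seasonality,
or measurement error in the loss product. Passing tests therefore
demonstrate that the estimators recover planted structure of the assumed
form, not that the form captures real Guiana Shield dynamics.

## Preprocessing

Three filters in fixed order, each idempotent: crown-cover threshold
(≥ 75 %, inclusive — the usual GIS convention), majority filter, exclusion
of swamp/mangrove polygons. The majority filter relabels a deforested pixel
with fewer than 2 deforested 8-neighbours (3×3 window) as never-lost, on
the any-year composite, iterated to a fixpoint so the operation is
idempotent; window, neighbour count and pass cap are configurable since the
original kernel is unspecified. Loss requires forest in 2000 and is
permanent (no regrowth), matching the loss-product semantics.

## Demo configuration

The bundled demo (`hfld.config.demo_config`) is a 300×300 landscape split
into two vertical-strip territories with planted gold-mining medians of
~0.45 ha/yr and demographic medians of ~0.3 ha/yr per territory against
~3,500 ha of available forest each — a deliberately HFLD-like regime in
which 35 years of historical behaviour clears under 1 % of the stock while
the ERB clears all of it, so the two-orders-of-magnitude scenario spread is
a structural property of the configuration, not a tuned outcome. Problem
sizes throughout (300×300 demo grid, 200×200 recovery landscapes, 100–200
trees, 10,000 Monte-Carlo draws, 200–500 recovery replicates) were chosen
as the smallest at which the statistics of interest are stable.

## Known limitations

* The GMM/NGMM split relies on distance-to-greenstone attribution; where
  gold mining occurs far from mapped belts the gold series is
  under-attributed and θ^V biased toward zero.
* sklearn's impurity importances are normalized to sum to one; rankings are
  unaffected but absolute MDG values are not comparable across models with
  different training sizes.
* The ERB terminal identity holds for the trajectory median; the allocated
  map matches it only to one pixel per year of rounding.
* Territory zones in the pipeline are vertical strips; arbitrary polygon
  zones are supported in the preprocessing API but not wired into the demo.
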