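# Methods

This note records the modeling choices, the synthetic study design, the
numerical conventions, and the limits of what the test suite shows.

## Data model and day definition

A civil day is fixed UTC−6 with no daylight-saving shifts; the loader
refuses timezone-annotated timestamps rather than converting, so the
contract is explicit. A station-day enters the analysis only when at
least 18 distinct hours carry a valid concentration; its targets are the
mean and the maximum of the available hourly values. "18 hours" counts
distinct observed hours, not wall-clock span. Duplicate station-hours
and negative concentrations are hard errors, not silently cleaned.

Seasons follow the Central-Mexico convention: cold dry (Nov–Feb), warm
dry (Mar–May), rainy (Jun–Oct). Seasonal strata pool across years.

## Predictors

Each feature row carries exactly 14 predictors in a frozen order:
projected x/y (meters), integer date index (origin at the first date of
the dataset — only differences matter to tree splits), the same-day IDW
interpolation of the dependent variable, Terra and Aqua AOD, a modeled
surface-PM layer, temperature (mean of the daily-max and daily-min
layers, K), precipitation (mm), vapor pressure (Pa), boundary-layer
height (m), two wind components (m/s), and static road density (m/km²).
For the daily-max target the sub-daily fields (modeled PM, boundary
layer, winds) enter as their 10:00 UTC−6 values: 10:00 is the modal
within-day peak hour of the station record, so mid-morning states are
the most informative for the daily maximum. Missing AOD is passed
through as NaN — XGBoost routes missing values natively — rather than
imputed; imputation would manufacture information precisely where the
satellites saw nothing.

### IDW conventions

Distances are planar Euclidean in projected meters; at the ~100 km scale
of the intended domains the geodesic correction is negligible, and the
synthetic fixture's projection is exactly planar. A target within ε = 1 m
of a source returns that source's value exactly (avoids division by
zero; a station colocated with a grid centroid reproduces its own
value). A day with zero same-day source observations has no defined
baseline; such rows are dropped and logged loudly — under realistic
missingness they are rare, and inventing a baseline would be worse.

Training rows always exclude their own station from their IDW sources.
Without this, the coincident-point rule would hand every training row
its own observation and the residual target would collapse to zero.

## Residual model

The ensemble is trained on `y − IDW` with the log-cosh objective; the
prediction adds the IDW back. The base score is pinned at 0 because the
target is already a residual. The IDW value is also available to the
trees as an ordinary predictor, letting splits modulate how much the
baseline is trusted. Trees are grown single-threaded with the exact
(non-histogram) method so fits are bit-reproducible; multithreading
would introduce nondeterministic floating-point reduction orders.

`log cosh r` is evaluated as `|r| + log1p(exp(−2|r|)) − log 2`, which is
overflow-free for any residual; gradient `tanh r` and hessian
`1 − tanh² r` are bounded by construction. The hessian vanishes for huge
residuals; the ridge penalty λ in the leaf-weight denominator keeps the
updates finite there.

### Hyperparameter search

The domains are trees ∈ {10, 25, 50, 100}, depth ∈ {3, 6, 9},
η ∈ [0.01, 0.5], λ ∈ [2⁻¹⁰, 2¹⁰]. η and λ are sampled on log scale
(both span ratios of 50× and 2²⁰; linear sampling would waste most of
the design on the top decade), discrete axes by equal-width binning of
the unit interval. The design is a maximin Latin hypercube: 50 scrambled
Latin-hypercube candidates are drawn and the one with the greatest
minimum pairwise distance kept — each candidate already stratifies every
axis, so maximin selection only improves space-filling.

Tuning is twofold station-wise cross-validation scored by MAE (the
evaluation loss; the log-cosh objective merely approximates it). Inside
each direction, the IDW baselines of both the training and the scored
rows are recomputed from the training fold's stations only, so the
scored fold's observations cannot leak into its own baselines. One
degenerate case is handled explicitly: when a training fold contains a
single station (possible in a 3-station study), own-station exclusion
would empty the source set, so that fold keeps the station's own
observation as its sole source — the residual target is then identically
zero and every candidate scores as the bare baseline, which is the
honest answer when there is nothing to learn from. Ties between
candidates break toward the earlier candidate, making tuning
deterministic.

## Leave-one-station-out evaluation

One fold per station; tuning runs nested inside each fold on the
training stations only, and every IDW baseline in the fold is computed
from the source set minus the held-out station. The test suite enforces
this with a perturb-and-compare guard: scaling the held-out station's
observations must leave every training-side feature bitwise unchanged,
and a deliberately leaky variant (kept in the code only so the guard can
be shown to catch it) must fail.

Metrics: MAE; MAD (mean absolute deviation of observations from their
median — the absolute-loss analogue of SD); RMSE; SD; and
R² = 1 − MSE/Var(observed). Variance and SD use the population
(divide-by-n) convention; R² is self-consistent under either convention
as long as one is fixed. MAD's median uses the midpoint convention on
even counts. Per-stratum R² uses that stratum's own variance.

## Exposure applications

* "Yearly" means are the mean of four calendar-quarter means (quarters
  Jan–Mar, Apr–Jun, Jul–Sep, Oct–Dec), which differs from the plain mean
  whenever coverage is unbalanced; an empty quarter makes the cell-year
  missing. Exceedance is strict (> 10 µg/m³ annual, > 41 µg/m³ daily).
* Cell population is the area-weighted mean of intersecting
  population-raster densities (exact axis-aligned interval-overlap
  arithmetic) times cell area; a raster gap under a cell is a hard
  error.
* Person-days of exceedance = Σ_cells persons × (days above the daily
  limit). The mean exceedance days per person is reported both
  population-weighted and unweighted.
* The per-day max:mean ratio is the ratio of spatial means (surfaces
  averaged over cells first); the mean of per-cell ratios is available
  behind a flag. Days are "rainy" when mean per-cell precipitation
  ≥ 1 mm.
* Rank correlations are tie-corrected Kendall τ-b (computed via scipy;
  the O(n²) pair-count definition serves as the oracle in tests).
  Conditional PM quartiles are computed per season within 0.1 °C
  temperature bins.
* Polygons receive the unweighted mean of annual means over cells whose
  centroids they cover; boundary centroids count as inside (closed
  polygons — a deterministic tie rule). Marginalization scores are
  grouped into 0.5-unit bins aligned at zero.

## The synthetic study

The generator emulates, at CI scale, the structure the analysis assumes:

* **Region** — a 20×20 planar grid of 927 m cells on a ~2250 m plateau
  with smooth ridges; the study region is the largest 4-connected
  component at or below 3000 m (edge adjacency: square cells share
  boundaries only on edges). Default ~340 cells, 8 stations.
* **Truth field** — log daily-mean PM2.5 = base (22 µg/m³) + season
  effect (cold dry +0.25, warm dry +0.10, rainy −0.25) + a static smooth
  spatial pattern (sd 0.30) + an AR(1) region-wide day effect (sd 0.25,
  ρ 0.6) + a day-varying smooth spatial anomaly (sd 0.20, correlation
  length 4 cells) + unstructured cell-day noise (sd 0.08). The
  day-varying smooth component represents synoptic ventilation and
  boundary-layer weather: it is what satellite and meteorology
  predictors can observe but sparse interpolation misses, and without it
  a toy region would make interpolation trivially optimal. The spatial
  covariance of real residual fields is unknown; the Gaussian-filtered
  white-noise construction is an assumption, exposed as config knobs.
* **Hours** — a unit-mean diurnal profile with a Gaussian bump peaked at
  10:00 (amplitude 1.8, day-jittered), so daily maxima run roughly twice
  the daily mean; hourly values get multiplicative lognormal measurement
  noise (σ = 0.3, unit mean — positivity and right skew), and each
  station-hour is independently dropped at the missingness rate (default
  0.1).
* **Predictors** — each dynamic predictor is a monotone transform of
  `w·s + √(1−w²)·noise`, where `s` is the standardized log truth, the
  noise is a fresh spatially smooth unit-variance field per day, and
  `w` is the informativeness (default 0.8). At w = 1 predictors are
  strictly monotone in the truth; at w = 0 independent of it.
  Boundary-layer height is anticorrelated with PM (shallow stable layers
  trap particles). AOD layers lose a random fraction of cells on a
  random subset of days (satellite coverage gaps). Temperature is
  emitted as daily max/min layers in K with a seasonal cycle and a
  signed PM coupling knob (default +0.5 °C per sd of log-PM anomaly).
  Precipitation occurs only on rainy-season days.
* **Population and polygons** — a density raster on its own grid,
  deliberately offset and coarser (×1.2) than the model grid, scaled to
  500 000 persons; six rectangular scored polygons stand in for census
  units.

With the default coupling, the toy region's *net* PM–temperature rank
correlation is negative: the cold dry season pairs high PM with cold
days and dominates the within-season coupling. The coupling knob
controls the planted dependence; the planted-effect tests therefore
switch the seasonal PM effects off so the knob's sign is the net sign.

### What passing tests do and do not show

The generator has smooth Gaussian fields, exact monotone
predictor-truth links, independent noise across predictors, and
stationary seasonal structure. Real aerosol fields have sharper sources,
retrieval artifacts correlated across satellites, instrument drift and
network heterogeneity — none of which are emulated. Passing tests show
the *machinery* is correct (leakage-free evaluation, faithful
arithmetic, reproducibility) and that the method recovers structure it
is designed to exploit; they do not certify accuracy on any real
monitoring archive.

## Problem sizes and runtime choices

The default study (20×20 grid, 8 stations, 2 years) runs
leave-one-station-out evaluation with nested tuning in about 40 s per
target on one CPU when tuning over 10 Latin-hypercube candidates, the
design size used by the acceptance script and the end-to-end tests; the
sampler defaults to 25 candidates for analysis use. The determinism
check runs the full pipeline twice at a reduced size (10×10 grid, 4
stations, 1 year, 3 candidates) and compares report files byte for
byte. Planted-effect recovery uses 100 replicates of a 10×10, 1–3 year
region (≥10⁴ cell-days each).

## Known limitations

* No uncertainty quantification on predictions; maxima especially would
  benefit from predictive intervals.
* No AOD gap-filling; rows never lose their IDW baseline to AOD gaps,
  but the trees see less signal on gap days.
* The "no same-day observations" rule drops prediction days entirely
  rather than falling back to a temporal model.
* Polygon linkage uses centroid membership, not areal intersection
  weights; small polygons between centroids are reported missing rather
  than estimated.
* Tuning uses a single random station split per call; repeated splits
  would reduce selection noise at proportional cost.
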