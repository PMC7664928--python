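# Methods

## Thermal-time model

Plant development is modelled as a function of accumulated heat. Daily
degree-days above a base temperature `T_b` are computed two ways:

* **Simple average** (`tavg`): `max(0, (Tmin+Tmax)/2 − T_b)`. Negative
  values are clamped to zero — below the base temperature vegetation is
  taken to be biologically inactive, and allowing negative contributions
  would make cumulative GDD non-monotone within a year. (Whether the
  historical simple-average variant clamps is genuinely ambiguous; clamping
  is this package's documented choice.)
* **Single sine** (`allen`): the day's temperature course is a single sine
  wave with mean `m=(Tmin+Tmax)/2` and amplitude `a=(Tmax−Tmin)/2`; the
  daily value is the day-average of degree-hours above `T_b`, with no upper
  cutoff. Because the average is over one full period, the phase of the wave
  (conventionally symmetric around the daily maximum) cannot affect the
  result, so it is documented rather than configurable. The closed form used
  is `[(m−T_b)(π/2−θ) + a·cosθ]/π` with `θ=arcsin((T_b−m)/a)` on the partial
  branch; it agrees with trapezoidal integration of the hourly sine to
  ~1e-8 °C·day (tested on 10⁴ random days) and meets the two trivial
  branches (`T_b ≤ Tmin`, `T_b ≥ Tmax`) continuously. A constant-temperature
  day (`a = 0`) degenerates to the simple average.

Accumulation always starts on January 1 (a convention of the method, not a
parameter), so input series must be gap-free from Jan 1 per location, source
and year; gaps are a hard error, never silently bridged. Day-of-year is the
standard calendar convention (Jan 1 → 1, Dec 31 → 366 in leap years); a
constant DOY offset cannot affect tree ensembles and only shifts linear
intercepts. The default base temperature is 10 °C, the de-facto standard for
olive; the sanity bound is `T_b ∈ [0, 45]` °C.

## Ordinal targets

BBCH codes are ordered labels whose numeric values carry no metric
information. An ordered rank map assigns 1..K; the shipped default is a
20-stage simplified olive scale whose exact stage composition is a synthetic
stand-in (real campaigns supply their own map). Regression outputs are
discretised back to ranks by round (default; implemented as `floor(y+0.5)`
to avoid banker's rounding), floor or ceiling, then clamped to `[1, K]`.
RMSE is computed on rank integers as-is, without ordinal re-weighting.

## Benchmark model

For each stage observed in training, the threshold is the *mean* cumulative
GDD of the training points with that stage; prediction returns the largest
rank whose threshold is ≤ the query GDD but below the next rank's threshold,
clamping below the first and above the last threshold to the extreme fitted
ranks. Decisions where the procedure is under-determined:

* Non-monotone fitted thresholds (possible with noisy data) are replaced by
  their running maximum over rank order, with a logged warning — this
  preserves interval semantics.
* A query exactly equal to the next threshold resolves upward (intervals are
  closed on the left, open on the right).
* Stages absent from training are never predicted; no interpolation.

A structural property worth knowing: because thresholds are within-band
*means*, a training point in the lower part of its stage's GDD band sits
below its own threshold and is predicted one stage low. Exact recall of a
training set is therefore only possible when each stage's GDD band is
single-valued; on realistic multi-location data the benchmark's accuracy
saturates well below 1 even with noise-free observations. This is the main
reason the benchmark trails the ML models.

## Evaluation protocol

Data are split 70/30 into train/test, repeated (100 times by default),
with stratification over (year × location) cells: per stratum the train
count is `round-half-up(0.7·n)`, strata of size 1 go wholly to train (no
test leakage is possible), and each repeat is a deterministic function of
(seed, repeat index). Metrics per repeat: exact-match accuracy, rank RMSE,
and the combined metric `(1 − Accuracy) × RMSE`, which is zero exactly when
classification is perfect and otherwise scales the error rate by how far
wrong predictions land. Across repeats, means are reported with Student-t
confidence intervals (95% default; the construction is a standard choice —
the interval is for the mean of the resampled metric distribution, repeats
are not independent samples of anything population-like). With a single
repeat the CI is undefined and reported as NaN.

Model comparison is *paired*: every candidate sees the identical sequence of
partitions (same split seed), so between-candidate differences are not
confounded by split noise. Selection is by minimum mean combined metric,
ties breaking to the earlier candidate. The same pairing is used across the
base-temperature grid, which makes the metric-vs-temperature curves smooth.

ML families are scikit-learn / xgboost regressors behind a uniform
fit/predict contract with discretisation to ranks; each family is available
with raw features or a degree-4 polynomial expansion (all monomials of total
degree 1–4, no constant). When a hyperparameter grid is supplied, tuning is
an inner loop of 3 repeats of 10-fold cross-validation confined to the
training split; the default grids are size-1 (library defaults), a modest,
documented approximation of generic automatic tuning that keeps a full
comparison cheap.

## Base-temperature optimisation

Grid search over 0–10 °C in 0.5 °C steps (21 candidates; configurable — the
≤10 °C cap reflects established practice for olive). At every candidate the
GDD features are fully recomputed, the scenario model is re-fitted over the
paired splits, and mean/SE/CI of each metric are recorded; per-metric optima
are argmax mean accuracy and argmin mean RMSE/combined, ties resolving to
the lower temperature (logged).

On synthetic worlds with known truth, the optimum of a *decision-tree*
scenario on the single GDD feature recovers the generating base temperature
to within one grid step (tested over T\* ∈ {2,4,6,8} °C, 20 replicate
worlds, 20 repeats per temperature). The *benchmark* scenario does not
recover it reliably: its within-band misclassification floor (see above) is
large, base-dependent in a world-specific way, and the global mean-threshold
model is misspecified across heterogeneous locations, so its predictive
optimum is displaced by 1–3 grid steps world-to-world even at 100 repeats.
That is a property of the benchmark, not of the optimiser; the tree scenario
has no such floor (splits sit at band edges) and yields a sharp profile.

## Synthetic worlds

The generator emulates a regional monitoring campaign, not physical climate:

* **Weather.** Daily mean temperature per location = annual mean + seasonal
  sine (peak near DOY 201) + AR(1) noise; Tmin/Tmax = mean ∓ half a fixed
  diurnal range. Defaults: 22 locations × 3 years (2008–2010), annual means
  ~N(14, 1.5) °C, amplitudes ~N(8, 0.8) °C, diurnal ranges ~U(7, 11) °C,
  AR(1) sd 2.5 °C with coefficient 0.6.
* **ERA5-like series.** The station series shifted by a per-location
  additive offset, drawn as sign·U(0.4, 1.6) °C: a grid-cell bias at a point
  location is systematic, can fall on either side of the station, and is
  rarely negligible. A constant temperature offset shifts every day's
  degree-days in one direction, so the cumulative-GDD relative error
  converges to a per-location constant late in the season (measured: sd over
  DOY 180–365 below 20% of the mean at every location). A multiplicative
  degree-day bias is not expressible as a temperature series and is not
  modelled.
* **Phenology.** The true stage at a visit is the number of thresholds
  crossed by cumulative single-sine GDD at the true base temperature
  (floored at stage 1); the observed stage is shifted ±1 with probability
  0.1 (misreading by one stage is the plausible field error; larger
  residuals must come from model failure, not injected noise). Twelve visits
  per location-year at roughly even days of year with ±3-day jitter give 792
  observations — the shape of a ~800-point campaign. Thresholds default to
  fixed fractions (0.02–0.90) of the climatological annual GDD total *at the
  true base temperature*, so the full stage scale is traversed each season
  whatever the true base is; absolute thresholds would leave late stages
  unreachable when the true base is high, which no real campaign would show.
  Accumulation and stages restart every January 1; there is no within-year
  threshold reset.

What the generator does **not** emulate: spatial correlation between
locations, elevation/topography effects, cultivar differences, weather-
dependent visit scheduling, multiplicative or seasonally varying reanalysis
bias, and any chilling requirement. Passing tests therefore demonstrate the
pipeline's correctness and the identifiability of its parameters under the
stated generative assumptions — not predictive skill on real orchards.

## Problem sizes and numerical choices

Default test/verification sizes: 10⁴ random days for the sine oracle
(trapezoid, 3×10⁴ steps, tolerance 1e-6), 10³ random fitted models for the
benchmark oracle, 100-repeat split contracts, 20 replicate worlds × 21 grid
points × 20 repeats for base-temperature recovery, and 20-repeat paired
comparisons for model ordering — sizes chosen so the full suite runs in
about a minute on one CPU while keeping every check adequately powered.
Seeds: a root seed spawns per-repeat and per-world streams via
`numpy.random.SeedSequence`; every CLI command and the acceptance script
accept `--seed`, and all reported numbers are deterministic given it.

## Known limitations

* The benchmark's mean-threshold construction caps its accuracy (see above)
  and makes it unsuitable as a base-temperature estimator.
* The default 20-stage rank map is a placeholder scale; real analyses must
  supply the campaign's own ordered code list.
* No hourly-temperature ingestion, double-sine/triangle methods, upper
  cutoffs, chilling units, or per-location benchmark variants.
* ERA5 retrieval is out of scope: the package reads CSVs already in its
  schema.
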