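# Methods

This note documents the models, parameter choices and numerical decisions
behind `sfamap`, and what the synthetic experiments do and do not show.

## Establishment-year convention

Every detector reports the **first calendar year of a persistent forest
spectral state** (not the last non-forest year).  This anchors the age
encoding (establishment 2020 → age 1, 1987 → age 34) and is applied
uniformly: MACD dates the first observation of a persistent BSI 0-crossing,
LT the first year after the recovery segment's base vertex, VCT the onset
of the eventually-confirmed forest state, CCDC the (floored) time of the
latest canopy-gain breakpoint.  Sub-annual times truncate to the calendar
year.

## Synthetic scene generator

The generator emulates a dense Landsat-like surface-reflectance record:

* **Spectral archetypes.**  Fixed six-band means for closed-canopy forest
  and bright bare soil (`sfamap.archetypes`), chosen so that BSI is
  negative/positive, NBR high/near-zero, and RED/SWIR much darker under
  canopy.  A pixel's spectrum is a convex mixture governed by a forest
  fraction w(t).
* **Establishment.**  w(t) follows a logistic centred on the **start** of
  the establishment year (rate 2 yr⁻¹ by default, a ~3-year spectral
  transition), so the establishment year is the first year spent mostly in
  the forest state — matching the convention above.
* **Partial convergence.**  Regrown stands converge to `mature_weight` =
  0.9 of the forest archetype, not 1.0.  Young and middle-aged stands stay
  measurably brighter in the SWIR bands than old growth for decades; this
  persistent margin is precisely what the data-driven IFZ threshold
  measures.  Were mature secondary forest spectrally identical to stable
  forest, a percentile threshold calibrated on one would be exceeded by the
  other at the complementary rate by construction, and threshold
  calibration would be meaningless.
* **Seasonality** is a single annual cosine per band (peak at year-fraction
  0.55), the minimum structure the CCDC harmonic model assumes.
* **Noise** is i.i.d. Gaussian per band and observation, default
  sd = 0.015 reflectance (typical surface-reflectance uncertainty).
* **Clouds** are i.i.d. Bernoulli per observation (default 30% in scene
  runs); masked observations carry cloud-like reflectance and a QA flag.
* **Transient canopy disturbance.**  A fraction of forest pixels (5% of
  stable, 25% of secondary by default) experience a canopy dip (depth
  0.30–0.45 of the forest fraction, duration 1.5–2.5 yr) that does not
  change land cover — thinning, insects, drought browning.  The recovery
  from such a dip is the canonical source of *false* CCDC breakpoints: on a
  secondary pixel it post-dates (and therefore, under the latest-break
  rule, displaces) the true establishment break.  This is the failure mode
  the random-forest break classifier exists to correct.
* **Determinism.**  Pixels are seeded by a stable `SeedSequence` of
  (seed, row, col), so scenes are bit-reproducible and tile-stable.

Default scene composition: 50% secondary forest, 25% stable forest, 12.5%
non-forest, 12.5% disturbed-then-recovered; establishment years uniform
1990–2018; span 1986–2021 at 8 observations per year.

What the generator does **not** emulate: radiative-transfer or topographic
effects, sensor differences, Landsat-7 gap geometry, spatially correlated
noise or phenology, mixed pixels, or gradual multi-decade degradation.
Passing tests therefore demonstrate the *logic* of the method under
controlled conditions, not its accuracy on real imagery.

## Detector parameters

| stage | parameter | default | rationale |
|---|---|---|---|
| MACD | window | 3 obs | smooths single-observation noise; mirrors VCT's two-year logic |
| MACD | persistence | 2 yr | a crossing must hold for two years |
| LT | max segments | 6 | matches the CCDC segment cap |
| LT | recovery threshold | 0.4 NBR | half the full bare→forest NBR contrast (~0.8); at 0.2, multi-year composite-noise drift in mature stands (~0.06 NBR per composite) qualifies as "recovery" |
| LT | despike | 0.9 | damp single-year departures >90% recovered (one parallel pass) |
| VCT | forest confirmation | 2 yr below threshold | the classical two-consecutive-year forest rule |
| VCT | non-forest confirmation | 3 yr at/above | one year longer than forest confirmation, so a 1–2 year canopy dip in standing forest is not a clearing; establishment is dated at the **onset** (first below-threshold year after the last confirmed non-forest run), so a single noisy above-threshold year neither delays nor resets it |
| CCDC | n_init / k_sigma / run | 12 obs / 3 / 6 obs | standard continuous-monitoring settings |
| CCDC | max segments | 6 | sufficient to represent land-cover change over the span |
| RF | trees / leaf size | 500 / 10 | leaf size regularises against residual label noise |

## Data-driven VCT calibration

Per 3° cell: reference b̄/SD are pooled over the stable-forest samples'
**annual composites** — the same observation type the detector consumes, so
the composite's seasonal phase cancels instead of biasing every z-score.
Cells short of 100 stable samples fall back to forest-map points restricted
to their final three observed years (they are only known to be forest at
the end of the record).  The IFZ threshold is the 95th percentile of the
pooled mature-phase (final three years) IFZ of secondary samples, clamped
at 0.5 to avoid degenerate zeros; cells with no secondary samples inherit a
configured global default.  An uncalibrated cell refuses to run detection.

## Breakpoint classification

Training labels are built without ground truth.  A sample's latest break is
**true** when all four basic algorithms detect at a consistent time — there
is a common anchor year within ±1 of every detection, i.e. the four years
span at most 2 — and the break is a canopy-gain break.  It is **false**
when no other algorithm places an establishment within ±2 years of it (no
independent corroboration).  Samples with partial corroboration but no full
consensus are ambiguous and excluded: labelling them false would fill the
false class with genuine establishments whose timing merely scattered, and
the classifier would learn to reject establishment signatures (measured on
synthetic scenes: out-of-bag accuracy drops to ~0.57 and ALB recall halves).

Break features are the 14 predictors: intercept, slope, three harmonic
cosine/sine pairs, the derived overall seasonal amplitude, RMSE, the break
magnitude (MAG, the mean signed residual of the triggering run), and three
topographic attributes (zero-imputed on flat synthetic scenes).  The
harmonic predictors come from a **canonical post-break fit** over a fixed
window (the first 12 clear observations after the break) rather than the
full following segment: the following segment's extent depends on where the
*next* break falls, which would make training features (latest breaks,
long ramp-plus-plateau segments) incomparable with the features ALB must
classify (earlier breaks, short steep segments).

No class re-weighting is applied — the label classes are near-balanced, and
re-weighting noisy labels cancels the majority vote within a feature
cluster.

## Ensemble rules

* `stack(overlay, baseline)`: the baseline's detections take priority; the
  overlay only fills its gaps.  Idempotent and associative; in scheme names
  "A + B", B is the baseline.
* `vote(maps, m, ±1 yr)`: the largest subset of per-pixel detections
  mutually within ±1 of the subset median wins if it has ≥ m members; the
  assigned year is the floored median (ties toward the earlier, i.e. older,
  stand; equally large subsets resolve to the earliest median).  A
  status-only variant (agreement on detection, not year) is available as a
  flag.
* `vcr2` = stack(VCT, stack(CCDC_RF_ALB, vote(4 basics, m=2))).

Detections after the product reference year (possible when the series
extends past it) are clipped to the reference year before age encoding;
detections before 1987 inside the forest mask encode as 36 (pre-span
forest).

## Numerical choices

* Harmonic least squares truncates singular values below 1e-6 of the
  largest; short cloudy windows can be numerically rank-deficient and an
  untruncated solve explodes the coefficients.
* Segment RMSE is degrees-of-freedom corrected (SS/(n−8)); the population
  estimate is biased low on the 12-observation initial window and roughly
  triples the false-break rate.
* The monitoring model refits on every clear observation until the window
  reaches 24 observations, then every 4th.
* A change test needs an RMSE floor (1e-4) so noiseless series cannot
  divide by zero.
* Reported accuracy percentages round half-up to two decimals via decimal
  arithmetic.
* Reference SDs below 1e-9 reflectance are treated as degenerate
  calibration input.

## Accuracy-assessment conventions

The confusion-count columns follow the published validation table that the
metric formulas are verified against: `commission = n_secondary −
correct_secondary` (secondary samples missed or mistimed) and `omission =
n_stable − correct_stable` (stable samples falsely detected).  Both
identities hold in every row of that table, and PA = cs/(cs+omission),
UA = cs/(cs+commission), OA = (cs+cst)/total then reproduce its printed
metrics; note these differ from the textbook omission/commission
definitions, which is documented rather than resolved.  Temporal tolerance
for a correct secondary detection is ±1 year.  Two cells of the source
table are internally inconsistent with their own row's counts; the
benchmark module stores the arithmetically consistent values and documents
both cases.

## Problem sizes

Synthetic experiments use sizes that exercise every code path while staying
laptop-friendly: detector/oracle suites of ~1,000 random series of length
≤ 40; a 50×50-pixel scene (2,500 pixels × 288 observations) for the
end-to-end recovery experiment; 100–150 samples per calibration check.

## Known limitations

* The LT segmentation interpolates through observed vertex values
  (bottom-up greedy merging); regression-based vertex fitting would be more
  robust to composite noise.
* The vote rule brute-forces subsets, exact but only sensible for the four
  basic algorithms.
* CCDC monitors a single index (NBR); the multi-band joint change score of
  full CCDC is out of scope.
* The best-available-pixel composite is single-criterion (distance to a
  target day of year).
* Real-data effects (sensor harmonisation, topographic illumination,
  mixed pixels) are untested by construction.
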