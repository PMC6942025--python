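# Methods

## Model

The package estimates the realised climatic niche of an invasive mosquito
from presence-only data by contrasting it with presences of native species.
The assumptions are:

* Each species' presence records sample its realised niche — the climate
  conditions it actually occupies, given dispersal and competition.
* The pooled native species occupy niches that overlap the invader's but
  differ in distribution, so a binary separator between "invasive" and
  "pooled native" records carries information about the invader's climatic
  limits. This replaces simulated pseudo-absences with real observations.
* Climate is summarised per 1 km × 1 km cell and calendar year by eight
  covariates: mean temperature of spring/March–May (T13), September (T09),
  October (T10) and December (T12) in °C; precipitation sums of February
  (P02), April (P04) and June (P06) in mm; and an autumn (Sep–Nov) drought
  index (D15, consumed as a supplied layer — its formula is the weather
  service's, not ours).

The separator is a C-SVM with RBF kernel on **raw-unit** covariates.
Defaults (`TrainingConfig`) and why:

| parameter | default | meaning |
|---|---|---|
| `gamma` | 5·10⁻⁴ | kernel width, calibrated to raw °C/mm scales; at typical covariate spreads the kernel distance is O(1) |
| `C` | 1.0 | soft-margin penalty |
| `tolerance` | 10⁻¹⁰ | optimizer stopping criterion |
| `per_species_cap` | 1000 | uniform subsample cap per species, mitigating the ~5:20:3:1 imbalance of the study design |
| `calibration_folds` | 5 | stratified folds for fitting the Platt sigmoid on out-of-fold decision values |
| `standardize` | off | z-scoring would silently change what `gamma` means; available only as an explicit flag |

Because the kernel acts on raw units, rescaling a covariate changes
predictions; this scale sensitivity is asserted in the test suite rather
than hidden behind automatic standardization.

Probability calibration uses `CalibratedClassifierCV(SVC(...),
method="sigmoid", cv=5, ensemble=False)`: the sigmoid is fitted on
cross-validated decision values, then the SVM is refitted on the full
training set. Probability is therefore a strictly monotone function of the
decision value, with the invasive species fixed as the positive class
everywhere.

Class prediction defaults to thresholding the calibrated probability at
0.5 (its natural decision point and the midpoint of the map legend bins);
a "raw" mode thresholds the uncalibrated decision value at 0 instead. The
two can disagree for points whose calibrated probability crosses 0.5 at a
nonzero decision value; agreement is checked empirically on separable toys.

## Validation

Temporal hold-out: train on years 2011–2014, evaluate on 2015. Reported
are the confusion matrix in both orientations, per-class precision, recall
and f1, and their observation-weighted means. Zero-denominator metrics are
reported as *undefined* (NaN with a flag), never as 0 — silent zeros would
corrupt the weighted means. Contexts that need a total order over
classifiers (GA fitness, Monte-Carlo null summaries) use a scoring variant
(`weighted_f1`) where a class the model never predicts contributes 0, the
standard scoring convention.

Predictive power at hold-out presences is summarised by the median, the
linear-interpolation quartiles (the common quantile default; nothing in
the design dictates another rule) and a 10-bin histogram of predicted
probabilities. Report tables round half-up to 2 decimals.

Per-variable class contrasts use the unpaired two-sided
Wilcoxon–Mann–Whitney test: exact null distribution when both groups have
n ≤ 20, otherwise the tie-corrected normal approximation. Raw p-values are
reported without multiplicity correction (a flag can enable it); the
contrast table is descriptive, not confirmatory.

## Variable selection

A wrapper GA over inclusion bitmasks: fitness = weighted f1 of a model
trained on the included variables under a stratified 75/25 hold-out with a
fixed per-run seed (k-fold available); the subsample cap is applied inside
each evaluation before the split. Operators: tournament selection (size
2), uniform crossover (rate 0.9), per-bit mutation at 1/n_candidates,
elitism 1 — standard settings, chosen once. The empty subset scores −∞.
With elitism the best-so-far trace is non-decreasing; nothing guarantees
the selected subset beats the full set, and the package does not claim it —
the implemented guarantee is parity with exhaustive search on small pools
(≤ 12 candidates), which doubles as the test oracle.

## Synthetic world

The virtual study system exists so that every stage has a testable input
with the statistical shape the analysis assumes.

* **Grids.** Each variable is a Gaussian-filtered white-noise surface
  (filter σ = 6 cells), standardized and scaled to a per-variable
  climatology (e.g. T13 ≈ 8.5 ± 1.5 °C, P06 ≈ 75 ± 25 mm), with a fixed
  spatial "geography" shared across years plus a per-year smooth anomaly
  (default 0.3 of the variable amplitude). Zero anomaly ⇒ identical years.
  Coordinates are abstract planar km, origin at the grid's top-left, no CRS.
* **Species.** A niche is a per-variable Gaussian response
  exp(−w((v−opt)/b)²), combined multiplicatively; cells are sampled with
  probability proportional to suitability and points jittered uniformly
  within the cell. Realised counts are Poisson around the configured
  abundance (simplest count model, variance testable); exact counts can be
  pinned for design-contract checks.
* **Scenario.** Four species — one invasive, three natives — with
  overlapping but distinct optima on all eight variables and yearly
  abundances 127:514:80:26 (the study's ≈5:20:3:1 imbalance, totalling
  508/2056/322/102 over four training years). Effect sizes are free
  parameters of the design; they were set once so that the classes
  overlap visibly yet separate (invasive offset ≈ +1 field-sd on the
  warm/wet flank, natives on the opposite flank), giving all-variable
  rank-test significance at study sample sizes and a recoverable niche.
  A `separation` knob scales the offsets; 0 collapses all four niches
  into one (the no-skill null). The "synthetic supplement" variant pins
  the exact study record counts, including the 2015 hold-out (308
  invasive; 115 native, split across natives proportionally to training
  abundance — the real per-species split is not recorded in the design).

What the synthetic world does **not** emulate: real geography and spatial
autocorrelation of sampling effort (citizen-science bias toward populated
areas), collinearity structure of real climate variables, coastal nodata
margins, or observation error in coordinates. Passing tests therefore
demonstrate the pipeline's correctness and its power under the assumed
niche structure — not field performance on real monitoring data.

For the no-skill null, the identical-niche replicates use class-balanced
abundances (invasive = pooled natives). With the study's ~1:2.8 imbalance
a majority-class collapse yields weighted f1 ≈ 0.63 by arithmetic alone,
so 0.5 is the meaningful chance level only in the balanced design.

## Data handling

* Point→cell mapping is nearest-cell containment on half-open cells; no
  interpolation. Each point maps to exactly one 1-km cell, matching
  gridded weather products.
* Records are joined to the stack of their own collection year; points
  outside the extent or on nodata cells are excluded and counted, never
  imputed. Duplicate records (same species/cell/year) are retained.
* Occurrence tables are CSV (or XLSX for convenience); rasters are ESRI
  ASCII grids with a YAML manifest — a plain-text format that round-trips
  values, nodata and geometry and keeps the whole artifact text-only.
  Model bundles are versioned joblib files carrying the estimator, the
  variable list, the full config and the seeds.

## Mapping

Whole-grid prediction evaluates the calibrated model on every valid cell
(all model variables finite); nodata propagates exactly. Evaluation is
chunked for memory safety, and per-sample kernel evaluation makes the
result independent of chunk size, bit for bit — asserted in tests. The
multi-year "colonisation potential" map averages the weather layers first
and predicts on the mean layers (average-then-predict). The alternative —
averaging yearly probability maps — is a genuinely different quantity under
a non-linear model; it exists as an explicit sensitivity mode recorded in
the raster provenance and is never substituted silently. Probability maps
are binned into 20 % classes (right-open except the top bin) for legends.

## Determinism

Every stochastic step (surface generation, occurrence draws, subsampling,
GA, calibration folds, hold-out splits) is driven by explicit seeds; the
experiment driver derives all stage seeds from one master seed via
`SeedSequence`, so a recorded config reproduces every report number
bit-identically.

## Problem sizes

The bundled scenario runs on a 50×50-km grid with five years and ~3400
occurrences, where a full simulate–train–validate–map cycle takes about a
second; the Monte-Carlo null uses 20×20-km single-year worlds with ~200
balanced points per replicate. The variable-selection driver caps each
species at 200 rows inside fitness evaluations, since wrapper selection
refits one model per candidate subset and the ranking signal survives the
tighter cap.

## Known limitations

* The native-contrast design estimates *separation from native niches*,
  not habitat suitability in an absolute sense; where niches truly
  coincide, the probability surface is uninformative by construction.
* Calibrated probabilities depend on the training class ratio after
  capping; they are comparable across maps from one model, not across
  models trained on different class balances.
* The GA's fitness is a noisy single-split estimate; on small pools the
  exhaustive oracle is preferable and provided.
* No dispersal, landscape or land-use modelling: the maps describe
  climatic suitability only, and multi-year averages can understate
  suitability in regions with strong inter-annual variability.
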