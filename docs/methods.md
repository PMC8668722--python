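# Methods

This note records the modelling conventions, the numerical choices made
where the design was genuinely open, what the synthetic generator does
and does not emulate, and the known limitations. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Grid model and distances

A study area is a regular longitude/latitude grid: row 0 is the
northernmost row, column 0 the westernmost, and coordinates refer to
cell centers. Every environmental layer is tagged `terrestrial` or
`marine` and carries a per-cell validity mask; a realm's mask is the
union of its layers' masks. A cell valid in both realms is **coastal**
and belongs to both realms simultaneously — this convention is what
makes the distance-to-the-other-realm variables well defined (zero
exactly on the coast) and lets a coastal cell inherit its own values in
the nearest-terrestrial design.

All distances are great-circle (haversine) distances between cell
centers on a sphere of mean radius 6 371 008.8 m. No map projection is
involved, so there is no high-latitude distortion to correct; the price
is the spherical-vs-ellipsoidal discrepancy, which is below 0.55 % of
the distance (worst case for near-equatorial paths against a WGS84
geodesic) and far below the grid resolution for the foraging-scale
distances that matter here. Cell areas use the spherical quadrilateral
formula, so high-latitude cells weigh less, consistent with the
distance kernel.

I/O is a gridded-CSV format: one file per layer listing only valid
cells, with the grid geometry, variable name and realm tag in `#`
header comments. Values are written with `repr` and parsed in
round-trip mode, so a save → load cycle is bit-stable. Files must agree
on shape and geometry to within 1e-9°.

## Cross-realm covariates

Nearest-cell searches minimise center-to-center great-circle distance;
exact ties break to the lowest (row, col). Coastal cells are their own
nearest other-realm cell at distance 0.

* **Terrestrial with marine.** For each terrestrial cell, the nearest
  marine-valid cell is its *nearest coast cell*; all marine cells whose
  centers lie within the species' mean maximum foraging distance
  (MMFD) of that coast cell form the sample set. Buffer membership is
  center-to-center distance ≤ MMFD. Each marine variable contributes
  its buffer mean (`mean_X`) and sample standard deviation
  (`X_variation`, n−1 denominator; a single-cell buffer yields 0 so
  one-cell coves stay modelable). The buffer always contains the coast
  cell itself, so it is never empty. Note the buffer is centred on the
  nearest coast cell, not on the terrestrial cell: for far-inland cells
  it can sample marine areas not actually reachable from the nest.
  This is deliberate; a distance-decay or accessibility-weighted
  aggregation is out of scope.
* **Marine with terrestrial.** Each marine cell inherits the local
  values of its nearest terrestrial cell (`nearest_Y` columns), reusing
  the same nearest-cell map that defines `distance_from_land`.
* **Distance layers.** `distance_from_sea` (terrestrial realm) and
  `distance_from_land` (marine realm) equal the nearest-other-realm
  distances and are zero on coastal cells. They serve as local
  covariates and background filters but are *not* aggregated or
  inherited across realms: the inherited copy would be degenerate (the
  nearest terrestrial cell of a marine cell lies on the coast, where
  `distance_from_sea` ≈ 0 identically).
* **Landmasses.** Connected components of the terrestrial mask
  (8-neighbour by default, 4-neighbour by flag) with spherical areas;
  isolation is the minimum distance to any strictly larger (by km²)
  landmass and is missing for the largest landmass — and for exact area
  ties at the top, since "larger" is strict. Landmass area/isolation are
  computed on demand but not auto-joined into model tables, precisely
  because isolation is undefined for the largest landmass and would
  inject missing rows into every terrestrial table.

## Sampling design

Terrestrial background: terrestrial cells within the coastal band
(default 20 km) of the sea. Marine background: marine cells within
`MMFD × exclusion_factor` of land. The MMFD is treated as a
90th-percentile foraging distance; how the implied 100th-percentile
radius follows from it is not standardised anywhere, so the factor is
an explicit configuration knob with default 10/9 (linear percentile
scaling). Setting it to 1 gives a plain MMFD cutoff.

Pseudo-absences are uniform draws *without replacement* from the
eligible background (background minus presence cells of the focal
realm; cross-realm presences do not constrain the other realm's
background). Replicate sets may overlap each other. Defaults follow the
full-scale design: 5 sets of 10 000, plus one balanced diagnostic set
sized to the presences (prevalence 0.5). Every set records its child
seed.

## Learners

The learner layer is a registry keyed by name; GLM, RF and ANN ship by
default and third-party learners can be registered. Because the
"default settings" of existing SDM frameworks are not a portable
specification, each shipped learner documents its own defaults, chosen
to mirror common SDM practice:

| learner | model | defaults |
| --- | --- | --- |
| GLM | unpenalised logistic regression | standardized covariates, linear + quadratic terms, no interactions |
| RF | random forest | 500 trees |
| ANN | multilayer perceptron | one hidden layer of ⌈√p⌉ units |

Iterative learners (GLM, ANN) attempt 100 iterations and escalate once
to 1000 on non-convergence; the convergence flag and iteration count
are recorded on the fitted model. Predictions are probabilities clipped
to [0, 1]. Fitting is deterministic given (data, seed); refits are
bit-identical.

Collinearity screening flags covariate pairs with |Pearson r| > 0.7 on
complete cases (constant columns are excluded with a warning). Rather
than dropping one member of each covarying pair at random and running
the alternative separately, the pipeline enumerates the candidate
variable sets exhaustively — 2^k sets for k disjoint pairs; overlapping
pairs form components whose maximal valid selections are enumerated —
and selects the set with the highest mean cross-validated TSS. This
subsumes the two-run random-drop procedure deterministically.

## Validation, ensembling, importance

Per pseudo-absence set, rows are split 70/30 stratified by class
(per-class counts rounded), models are calibrated on the training split
and scored on the validation split; the process repeats five times with
fresh split seeds. The TSS threshold is chosen by scanning a 0.001 grid
on [0, 1] and maximising TSS on the evaluation split (ties to the
smallest threshold); sensitivity, specificity, TSS and ROC AUC are
reported per record, and summaries are mean ± SD.

Ensembles include a full-data model per (learner, pseudo-absence set)
whose **cross-validated** mean TSS strictly exceeds the gate (default
0.6). Gating a full-data model on its own training TSS would be
circular, so the cross-validated TSS both gates and weighs. Member maps
are min–max rescaled to [0, 1] over the projected cells (rank-
preserving, so Spearman diagnostics are unaffected by the choice of
scale), then combined per cell as the TSS-weighted mean; uncertainty is
the unweighted across-member population variance (zero when members
agree, including singleton ensembles). The validation-vs-full check is
the Spearman rank correlation between the ensemble built from the
repeat-0 training-split models and the full-data ensemble over the same
cells.

Variable importance is permute-and-repredict: shuffle one covariate
column (seeded), re-predict with the *fitted* model, and report
`1 − r` (Pearson correlation between reference and permuted
predictions) clipped to [0, 1], averaged over 10 permutations with its
SD. The alternative reading — refit the model with the randomized
variable — was rejected because the 0-to-1 scale with "0 = no impact"
anchors the repredict convention: a model that provably ignores a
variable scores exactly 0. Models whose reference predictions are
constant have undefined importance and are flagged, not filled.

## Seeds

All stage randomness derives from the single study seed through
`numpy.random.SeedSequence([seed, stage, *indices])`, with fixed stage
identifiers for pseudo-absence draws, splits, learner fits, permutation
importance and synthesis. Learner seeds are reduced modulo 2³¹. A run's
manifest (config snapshot, input/output SHA-256 hashes, seeds,
versions, timings) therefore suffices to reproduce every output file
byte for byte.

## Synthetic worlds and the reference study

`generate_seascape` thresholds a smoothed Gaussian random field at its
median to split the grid into land and sea; land cells bordering sea
form a one-cell coastal fringe valid in both realms. Environmental
layers are independent Gaussian random fields (white noise smoothed at
a 4-cell length scale, standardized within their realm). A
`VirtualSpecies` defines true suitability as the inverse logit of a
linear combination of (z-scored) covariates, which may include
cross-realm features such as `mean_mar_0`; presences are independent
Bernoulli draws with probabilities rescaled so the expected count hits
a target.

The packaged reference study (`mrsdm.study`) uses 60×60 worlds at
5 arc-min resolution, a 40 km MMFD (the Atlantic puffin's published
mean maximum foraging distance), ~300 presences, 300 pseudo-absences
per set (≈ prevalence 0.5 at this grid scale — the full-scale default
of 10 000 exceeds the entire background of a synthetic world), two
replicate pseudo-absence sets, five repeated splits, and GLM + RF +
ANN. The virtual seabird weighs a terrestrial field and a marine
foraging-buffer mean equally (coefficients 3.0 per SD, intercept −4),
giving a sharp range occupying roughly a sixth of the land. The
sharpness is intentional: real occurrence data of this kind derive from
rasterized range polygons, where essentially every suitable cell is a
presence, and it is what lets single-realm models retain substantial
(gate-passing) skill while still missing the marine half of the signal.
The two pseudo-absence sets and the 60×60 scale are the package's own
benchmark sizing.

What the generator does **not** emulate: spatial bias and error in
occurrence records, correlated environmental layers, anisotropic or
trending fields, observation effort, dispersal limitation, and
range-edge disequilibrium. Passing the synthetic benchmark shows the
machinery recovers known cross-realm signal under clean conditions; it
does not certify performance on real, messy data.

## Degenerate inputs and numerical conventions

* Empty other-realm mask → domain error; empty backgrounds warn; a
  pseudo-absence request exceeding the eligible pool raises an error
  naming the shortfall.
* Single-class labels → fit/metric errors; per-record failures inside
  repeated validation are recorded in the table, not fatal.
* Constant covariates are excluded from screening (warning); constant
  member maps cannot be rescaled and are rejected (such a model cannot
  pass the gate).
* Standardisation guards zero variance by leaving such columns
  unscaled.
* Buffer SD with one sample is 0, not missing.

## Limitations

* Nearest-cell and buffer semantics are center-to-center; sub-cell
  coastline geometry is invisible at grid resolution.
* No reprojection/resampling: all layers must share one grid.
* No spatial cross-validation, target-group backgrounds, spatial
  thinning, or distance-decay foraging kernels.
* GAM and MAXENT-style learners are not shipped; the registry accepts
  them as third-party registrations.
* The four designs assume the focal realm's presences are complete
  within the study area; mixed-realm occurrence sets are split by realm
  before modelling.
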