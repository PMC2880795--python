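# Methods

## The analysis chain

The package implements a five-stage chain for two-group ERP studies:

1. **Preprocessing** — epochs of filtered EEG are average-referenced and
   rejected when any channel exceeds 100 µV in raw amplitude, 35 µV in
   the 20–35 Hz band, or 50 µV in the 0–1 Hz band; surviving epochs are
   averaged into one ERP per subject per condition.
2. **Decomposition** — Infomax ICA is fitted to the horizontal
   concatenation of all subject ERPs (channels × Σtime), separately per
   task condition, yielding an unmixing matrix `U` and per-component
   spatial filters `Fᵢ = U⁻¹U_zᵢ`.
3. **Feature extraction** — for each retained component, the
   back-projected time course at its dominant electrode is scanned with
   sliding windows; each window yields the extremal amplitude (µV) or
   its latency (ms).
4. **Selection/classification** — greedy forward selection of M
   features by 10-fold cross-validated SVM accuracy; accuracy,
   sensitivity and specificity from pooled out-of-fold predictions.
5. **Statistics** — pooled two-sample Student t tests, either pointwise
   along component time courses (uncorrected p < .05 mask) or from
   printed summary tables.

## Infomax ICA

The estimator maximizes the joint entropy of logistic-transformed
source estimates (Bell–Sejnowski), equivalent to maximum likelihood for
super-Gaussian sources — appropriate here because averaged ERP
deflections are sparse in time.  Implementation choices:

* **Whitening and rank.**  Rows are centered and PCA-whitened.
  Average-referenced data are exactly rank-deficient (channel columns
  sum to zero), so a square whitening of all 19 channels does not
  exist.  The fit therefore detects the numerical rank r (relative
  singular-value threshold 1e-10) and runs a square ICA inside the
  r-dimensional subspace; topographies are mapped back through the
  pseudoinverse.  With full-rank input this reduces to ordinary square
  Infomax, and the filters sum to the identity; with reduced rank they
  sum to the projector onto the retained subspace, and the data-level
  decomposition `ΣᵢPᵢ = P` still holds exactly for any data in that
  subspace.  `n_components=None` (strict square) raises on
  rank-deficient input; `"rank"` reduces automatically.
* **Updates.**  Natural-gradient ascent over shuffled mini-batches
  (default block ≈ 5·ln T, capped at 512); learning rate 1e-3, annealed
  ×0.9 whenever the weight-update direction turns by more than 60°;
  stop when the per-pass relative weight change falls below 1e-7 or at
  `max_iter` (1024 for library calls; the pipeline uses 2048 passes
  with block 128, which on benchmark-sized inputs reaches the same
  recovery quality as a FastICA reference).  Diverging weights trigger
  a halved rate and a fresh orthogonal start.
* **Conventions.**  Components are ordered by descending power of their
  rank-1 back-projection on the fitting data; signs are fixed so the
  largest-|weight| electrode of each topography is positive.  With
  these conventions, fits from different random seeds agree to high
  precision on identifiable mixtures.
* Explained power of a component subset is defined as the power of the
  summed back-projection divided by the total power of the input
  (reconstruction-power ratio), not the sum of per-component powers.

## Synthetic cohorts

`erpica.synth` generates what the chain assumes: K ≤ 19 latent sources
with fixed scalp topographies (random patterns anchored at
physiologically sensible electrodes, projected to zero mean and unit
norm — zero mean makes the noiseless mixture average-referenced by
construction) and time courses that are sums of Gaussian bumps, so
every extremum latency is analytically known.  The stock seven-source
set mirrors a 3 visual + 3 executive + 1 novelty design: three sources
active in both NOGO and NOVEL conditions, three NOGO-only, one
NOVEL-only.  Bump centers are staggered (100–510 ms) so source time
courses overlap little; temporal independence is an assumption of the
decomposition, and the stock cohort is built to satisfy it.  Real ERP
components overlap more and are correspondingly harder to separate —
passing recovery tests here demonstrates correctness of the estimator,
not that every real dataset is separable.

Between-subject variability: per-subject, per-source latency jitter
(Gaussian, ms) and relative amplitude scaling (Gaussian, default 0.3 in
the benchmark).  Amplitude variability across subjects is what renders
the *group-level* mixture identifiable in the noiseless limit; it is a
real feature of ERP cohorts.  Group effects are applied to the case
group only: per-source latency shifts (applied to the analytic bump
centers, never by circular sample shifting, so a shift that pushes a
bump outside the epoch raises an error) and amplitude scale factors.

Sensor noise is Gaussian per channel and sample; optionally band-limited
(zero-phase 4th-order Butterworth) to 0.5–50 Hz, matching the
acquisition filtering of the recordings the simulation emulates.  The
benchmark uses band-limited noise; white noise remains available and is
the plain default of `SimConfig`.  Bump amplitudes are waveform-level
µV; because topographies are unit-norm, the dominant electrode carries
roughly half of the waveform value, and the stock amplitudes (8–12 µV)
put scalp deflections in the 4–6 µV range typical of task components.

### The packaged benchmark

`benchmark_config()` fixes the study conditions of the end-to-end
benchmark: 74 + 74 subjects, the NOGO trough source at Cz/C3 (310 ms,
−12 µV waveform) delayed by 40 ms in the case group, subject latency
jitter 8 ms (one fifth of the shift), amplitude jitter 0.3, sensor
noise 1.5 µV band-limited to 0.5–50 Hz (commensurate with the residual
noise of an average over ~100 trials).  No effect sizes are published
for the cohorts this emulates, so the shift magnitude is a package
choice: large enough to be detectable by a latency feature, small
relative to the epoch.

The pipeline keeps 6 components from the NOGO decomposition and 1 from
the NOVEL decomposition (the 6 + 1 continue-set/novelty design), maps
each to its dominant electrode, and enumerates a scaled-down template
(100 ms windows, 8 ms step, 0–600 ms, all four extremum/return
combinations: 1764 features) rather than the full reference template
set ({50,75,100,125,150} ms windows at 4 ms steps: 17 584 features,
available via `reference_templates()`); the scaled template keeps a
forward-selection run in the minutes range while preserving the
structure of the search space.  Selection uses M = 5, RBF kernel,
C = 1, gamma = "scale", stratified 10-fold CV with a fixed seed;
features are standardized with training-fold statistics only.  The
linear kernel is evaluated on the feature set selected under the RBF
kernel (a single shared selection keeps the two numbers comparable and
halves the cost).

On the packaged benchmark the planted component is recovered at
|topography correlation| ≈ 0.99, the first selected feature is a
latency-of-minimum feature on that component, and both kernels classify
at or above 95 % — the numbers are printed by the README's worked
example and recomputed by `scripts/acceptance.py`.

**Known limitation.**  A latency shift of a trough creates two
near-equivalent detectors: the latency of the window minimum (the
physiological reading) and the latency of the window *maximum* in
windows where the trough depresses one edge (a window-edge artifact of
sliding-window extremum features).  Their cross-validated accuracies
differ by fractions of a percent, so which one the greedy selection
picks first can flip with the noise realization; the packaged benchmark
is a fixed configuration.  In every realization examined the first
feature is a latency feature on the shifted component.

## Artifact generator

`simulate_artifact_epochs` plants each artifact at least 10 % beyond
its own threshold while staying at least 10 % inside the other two
rules: smooth 150 µV transients (σ = 25 ms, spectral energy near 6 Hz)
for the amplitude rule, 60 µV oscillations at 27 Hz for the fast rule,
and 75 µV baseline offsets for the slow rule, over quiet alpha-band
backgrounds.  Thresholds are strict inequalities (a value exactly at
100 µV is kept).  The band criteria are measured as the maximum
absolute value of a zero-phase 4th-order Butterworth filtered trace —
one defensible reading of "µV in band"; peak-to-peak or RMS readings
would need different planted margins.

## Statistics

Pooled-variance (classic Student) t throughout, since the reference
df = 146 = 74 + 74 − 2 implies pooling; two-sided p-values; no
multiple-comparison correction in the pointwise masks (matching the
reference analysis style, and flagged as such).  t statistics
recomputed from the printed group summary tables reproduce the printed
values to within 1 %; residual discrepancies stem from rounding of the
printed means and standard deviations.

## Numerical and degenerate-input choices

* Latency features report time relative to stimulus onset; extremum
  ties break to the earliest sample.  Windows are closed intervals on
  the ms axis; a window may end one sample step past the last sample,
  matching the half-open [0, 600 ms) epoch convention.
* Template expansion stops when `t0 + window > end` ("the window
  reaches the end point"); the count obeys
  `floor((end − window − start)/step) + 1`.
* Forward-selection ties break to the lowest feature index; the
  selection criterion is the same single-loop CV accuracy that is
  reported (the reference protocol, optimistic); `nested_cv_evaluate`
  provides the unbiased variant.
* Zero pooled variance with equal means gives t = 0; with unequal
  means it is an error (infinite t).  All-rejected epoch sets, empty
  feature subsets, single-class labels, rank-deficient strict-square
  ICA fits, and out-of-range component indices raise descriptive
  errors.
* Split-half stability sorts subject ids before splitting (invariant
  to dataset ordering), fits each half's grand average, and matches
  components greedily by |topography correlation|.  The pipeline
  restricts the stability fits to the number of retained components,
  measuring the stability of the components actually analyzed rather
  than of the residual noise space.

## Scope

Source localization (and with it anatomical component naming), raw
continuous-EEG simulation, eyeblink generation and correction on
continuous recordings, non-parametric statistics and multiple-testing
correction are out of scope.  Component removal is provided as the
algebraic operation `(I − ΣFᵢ)P` for any supplied decomposition.
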