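# Methods

`oculoscreen` analyses free visual exploration (FVE) of face stimuli: a
participant views each image for 10 s with no task other than to look,
while a screen-mounted eye tracker samples gaze at a nominal 90 Hz on a
1920×1080 display (23.8″, viewed at 70 cm with a chin rest). The package
covers the full analysis chain — cleaning, event segmentation, an
11-feature oculomotor battery, scanpath similarity, reliability surfaces,
two-group statistics and subject-level classification — together with a
synthetic cohort generator that emulates a two-group (control vs impaired)
screening study.

## Geometry

Pixels are assumed square; the physical pixel pitch is derived from the
screen diagonal and resolution, and a displacement of `d` mm on the screen
subtends `atan(d / D)` degrees at viewing distance `D`. No off-axis
correction is applied: at the eccentricities that matter here (≤ 15°) the
flat-screen error is below the tracker's 0.5–1° accuracy.

**Units.** Feature names follow the field's convention of degrees (deg,
deg/s, deg²). A `units="px"` mode emits raw pixel quantities instead,
because published magnitudes for this paradigm are sometimes printed in
pixel-scale numbers under degree labels (e.g. saccade "amplitudes" above
100), and pixel output makes such comparisons possible without guessing.

## Preprocessing

Cleaning runs in a fixed order:

1. **Blink excision.** Maximal invalid runs lasting 75–500 ms are
   classified as blinks and removed together with one flanking sample on
   each side (lid closure and reopening distort the reported position).
   Removed samples are never interpolated and never enter event detection.
   The duration window is a heuristic — trackers do not label blinks in
   this export format — and both bounds are configurable.
2. **Gap interpolation.** Remaining invalid runs strictly shorter than
   75 ms, flanked by valid samples, are filled linearly in x and y. Gap
   duration is measured between the flanking valid samples minus one
   nominal sample interval, which is robust to timestamp jitter.
3. **Trial quality control.** A trial is dropped when the fraction of
   samples still missing exceeds 20% (strict inequality at the boundary).

Running blink removal first is what makes the other two rules coherent: a
blink is *removed* rather than *filled*, so it must be exempt from
interpolation. Sample counts and timestamps are never altered by any step.

## Event detection

The default detector is I-VT (velocity-threshold identification).
Point velocities are central differences over two sample intervals,
converted to deg/s; samples below 30 deg/s form fixation candidates.
Central differencing halves jitter noise — at 90 Hz and ~5 px sample
jitter, single-interval velocities alone would cross a 30 deg/s threshold
on roughly a tenth of genuine fixation samples — but it blurs each event
boundary by one sample. A refinement pass therefore reclaims boundary
samples whose single step into the fixation run is sub-threshold, which
restores event durations to within one sample interval on noise-free
input. Candidates shorter than 60 ms are discarded; supra-threshold
material between retained fixations becomes a saccade. Events never merge
across blink-removed or missing samples.

Saccade amplitude is the vectorial displacement between the flanking
fixation centroids — robust to sample noise — while the path-integrated
notion of distance lives in the scanpath-length feature. Mean saccade
velocity is amplitude over duration; peak velocity is the maximum point
velocity within the saccade window (floored at the mean so the invariant
peak ≥ mean holds even for one-sample saccades). The 30 deg/s / 60 ms
defaults are standard for ~90 Hz consumer trackers; a dispersion-based
detector (I-DT) is available via `detector="idt"`.

## The 11-feature battery

Saccadic: mean vectorial velocity, mean vectorial amplitude, inflection
count, mean peak velocity, velocity-waveform indicator. Fixation: mean
fixation duration, fixation count, regions of interest. Scanpath: Shannon
entropy, scanpath length, scanpath area.

Notable definitions and choices:

* **Inflection count** — sign changes of the horizontal plus vertical
  displacement components across consecutive saccades; components with
  magnitude ≤ 1 px inherit the previous sign so tracker noise cannot flip
  a direction.
* **Velocity-waveform indicator** — the OLS slope relating per-saccade
  mean and peak velocity. The default regresses mean on peak (slope < 1
  for stereotyped velocity profiles); the opposite orientation is a
  configuration switch because published usage is ambiguous about the
  axes. It is the one battery feature whose group direction this package
  does not assert.
* **Regions of interest** — single-linkage clusters of fixation centroids
  cut at 1.2°, counting clusters with ≥ 2 member fixations ("concentrated
  attention"). The 1.2° default is deliberate: facial landmark regions on
  a 600×450 px face at this geometry are ~3° apart, and a radius much
  above half that spacing lets single-linkage chaining merge them — at
  2°, denser scanpaths (more fixations) paradoxically yield *fewer*
  regions. The radius and membership threshold are configurable.
* **Shannon entropy** — fixation occupancy over an 8×8 grid of screen
  cells, reported in bits with the Miller–Madow correction
  `+(K−1)/(2n ln 2)` by default. The plug-in estimator is biased downward
  at small fixation counts, so two groups that differ in how *many*
  fixations they make would appear to differ in dispersion even when they
  explore identically; the corrected estimator compares dispersion, not
  sample size. `bias_correction=None` restores the plug-in value.
* **Scanpath length / area** — summed centroid-to-centroid distances, and
  the convex-hull area of the centroids (zero below three non-collinear
  points). Both are defined over fixation centroids, consistent with the
  similarity analysis operating on fixation sequences.

Features that are undefined for a trial (no saccades, no fixations, fewer
than three saccades for the regression) are NaN, never zero.

## Scanpath similarity

Two scanpaths are compared by global sequence alignment over their
fixation sequences. Substituting fixation *i* for *j* costs
`|dᵢ−dⱼ|·m^dist + (dᵢ+dⱼ)·(1−m^dist)` where `dist` is their separation in
degrees and the modulation `m = 0.83` per degree controls how quickly
distant fixations stop counting as matches; insertions and deletions cost
the fixation's duration. This is the scasim cost design. The minimal
total cost never exceeds the summed duration of both paths, so
`d_norm = cost / (dur_a + dur_b)` lies in [0, 1] and the default
similarity is `s = 1 − d_norm`. Absolute similarity levels depend on this
normalisation choice; analyses should interpret orderings (e.g.
within-subject vs between-subject), not absolute values.

Intra-individual similarity averages over a subject's trial pairs;
inter-individual similarity averages over subject pairs of a group on the
same stimulus, then over stimuli.

## Reliability

The AOI analysis uses one standardized 600×450 px rectangle over the core
facial features (boundary-inclusive membership) and reports the proportion
of fixation points and of fixation time inside it. ICC uses the two-way
model on subjects × first-k-trial matrices (k = 3, 5, 7); the default form
is ICC(3,k) — two-way mixed, consistency, average of k measures — because
the question is the internal consistency of a feature averaged over a
fixed trial set; ICC(2,1) is available for absolute agreement. "First k
trials" counts retained trials in presentation order: dropped trials are
skipped, not imputed. Degenerate matrices (identical columns) report 1.0
with a warning.

## Group statistics

Each feature is compared between cohorts behind a Shapiro–Wilk gate
(α = 0.05 per group): both normal → independent two-sample t-test with
Cohen's d; otherwise two-sided Mann–Whitney U with rank-biserial
r = 1 − 2U/(n₁n₂). Effect-size CIs are percentile bootstrap (10,000
seeded resamples). No multiple-testing correction by default (a Holm
option exists). The unit of analysis defaults to subjects (trial means),
which respects the nesting of trials within subjects; a trial-level mode
treats each trial as an observation for comparability with analyses that
report trial-scale degrees of freedom. The trial-level mode overstates
the effective sample size and should be read accordingly.

## Classification

The feature table is strictly one row per subject — per-trial features
spread into (feature, trial) columns — so no subject can leak between a
training fold and its own test fold. A subject with fewer retained trials
has missing cells filled with their own per-feature median. Inside every
leave-one-out fold, the scaler, the L1-logistic selection and the
classifier are re-fit on the training subjects only; selection tunes the
penalty by bisection until exactly 10 columns survive (the nearest
achievable count below 10 is taken, flagged, when a regularisation-path
plateau makes 10 unattainable). A `global_selection` switch reproduces
the leaky select-once-on-everything variant for comparison.

Classifiers are fit with balanced per-fold sample weights. Leave-one-out
folds are intrinsically class-imbalanced (the held-out subject's class is
under-represented in training), which tilts scores toward the majority
class and drags the pooled null AUROC well below 0.5; balanced weighting
restores chance level and is the appropriate default for imbalanced
cohorts in any case. The four families are an RBF-kernel SVM (C = 1),
extremely randomised trees (200 trees), and two gradient-boosted tree
variants — XGBoost and LightGBM — with shallow trees (depth 3, 150
rounds, learning rate 0.1) and minimum-child settings small enough that
splits remain possible at leave-one-out fold sizes of small cohorts.
Accuracy and F1 come from pooled hard predictions; AUROC and AUCPR from
pooled continuous scores, since per-fold curves are undefined with one
test sample.

## The synthetic cohort generator

No public dataset accompanies this paradigm, so study-level behaviour is
emulated. A trial alternates fixation epochs (log-normal durations, mean
300 ms for controls, σ_log = 0.4; positions jittered isotropically, 5 px)
with minimum-jerk saccade ramps whose durations follow a main-sequence
rule (2.2 ms/deg + 21 ms). Fixation locations are drawn from a mixture of
seven facial anchor regions (eyes, nose, mouth, brow, cheeks) with
scatter 25 px, plus wider "excursion" fixations arriving at a fixed rate
of 4 per trial (SD 280×210 px). Blinks arrive as a Poisson process
(0.25/s, 100–300 ms) and 2% of samples are dropped at random.

Impairment is injected with one multiplicative factor per effect family,
chosen so the *detected* feature ratios approximate the magnitudes this
kind of cohort shows (case/control ≈ 1.16 for fixation duration, ≈ 0.86
for amplitude):

* the dwell factor (1.07) and rate factor (0.98) lengthen fixations,
  which mechanically lowers the fixation count in a fixed 10-s trial;
* the amplitude factor (0.86) acts through *ordering*: the trial's
  fixation set is visited nearest-remaining-first with probability
  `(1 − factor) × 1.9`, shortening saccades and scanpaths without moving
  the spatial distribution;
* the extent factor (0.75) contracts excursion radii, but only beyond
  0.9 SD, shrinking the hull extremes.

This architecture is deliberate: the *set* of fixation locations is
(nearly) identically distributed across groups, and excursions arrive at
a group-independent temporal rate, so gaze-dispersion entropy is matched
between groups by construction while amplitude, velocities, counts,
scanpath length/area and region counts all shift in the impaired
direction. That reproduces the empirical pattern this paradigm shows —
many strongly significant oculomotor differences alongside a null
entropy difference — which a naive "shrink everything" generator cannot:
any global spatial contraction drags entropy with it.

Subject idiosyncrasy comprises a per-subject duration multiplier
(log-normal, σ = 0.06), a spatial offset of the whole fixation pattern
(σ = 80 px), a shift of the ordering-locality (σ = 0.05), and per-subject
anchor preferences (Dirichlet, concentration 60). These make a subject's
scanpaths more similar to each other than to other subjects' — the
intra- vs inter-individual structure — and give features the
between-subject stability that ICC measures. Impaired subjects
additionally carry an *impairment profile*: each group factor is applied
as `factor^gain` with per-subject log-normal gains (σ = 0.6, mean 1), so
one case is mostly dwell-affected and another mostly amplitude-affected,
mimicking lesion heterogeneity. The profile is what makes integrating
feature families genuinely useful for classification: each single family
misses the patients whose impairment expresses elsewhere.

**What the generator does not emulate:** pupil dynamics, smooth pursuit
(static stimuli), vergence, drift/calibration decay within a session,
stimulus-specific saliency differences between face images, and any
relationship between lesion topology and specific oculomotor signatures
beyond the random profile. Passing tests on simulated cohorts therefore
demonstrate that the pipeline recovers what the generator injects at
realistic noise levels and sample sizes — not that real recordings would
show these effects.

## Numerical and procedural choices

* Velocity computation and boundary refinement as described above; ties
  and degenerate inputs (fewer than two usable samples, all-invalid
  trials) return empty results with warnings rather than raising.
* The exactly-k bisection runs on log-spaced C ∈ [1e−4, 1e4], ≤ 40
  steps, liblinear, 1000 iterations; non-convergence at interim penalty
  values only affects the split search, not the final model.
* ICC values are clipped below at −1; identical-column matrices short-
  circuit to 1.0 (the ANOVA ratio is 0/0).
* All simulation randomness flows through one `numpy` Generator seeded
  from the cohort specification; identical (spec, seed) pairs are
  bit-reproducible.
* Simulation-based test sizes (replicate counts, cohort sizes) are chosen
  to hold Monte-Carlo error comfortably below the asserted bands while
  keeping the default suite fast on a single CPU.

## Known limitations

* The I-VT threshold is global; glissades and post-saccadic oscillations
  are folded into whichever event they adjoin.
* The similarity normalisation bounds similarity in [0, 1] but its
  absolute level is convention-dependent; only orderings are meaningful.
* Trial-level statistics treat trials as exchangeable observations; a
  mixed-effects treatment of the trial nesting is out of scope.
* The generator's effect architecture is a model of *this paradigm's*
  reported group structure; transferring conclusions to other tasks
  (pursuit, anti-saccade) requires different generative assumptions.
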