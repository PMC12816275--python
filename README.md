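# oculoscreen

Oculomotor feature analysis of free visual exploration, built for
screening studies that compare a clinical group against controls with a
consumer eye tracker. During free viewing of face images, neurological
impairment shows up as longer and fewer fixations, smaller and slower
saccades, and a shorter, less extensive scanpath; `oculoscreen` turns raw
gaze samples into those measurements and into subject-level screening
classifiers, end to end:

* **preprocessing** — blink excision (75–500 ms validity gaps), linear
  interpolation of gaps < 75 ms, drop trials with > 20% missing data;
* **event detection** — I-VT segmentation (30 deg/s, 60 ms minimum
  fixation) with point-to-point boundary refinement; I-DT alternative;
* **features** — an 11-feature battery in three families: saccadic (mean
  vectorial velocity, amplitude, inflection count, peak velocity,
  velocity-waveform slope), fixation (mean duration, count, regions of
  interest), scanpath (Shannon entropy of gaze dispersion, scanpath
  length, convex-hull area);
* **scanpath similarity** — duration-weighted sequence alignment
  (scasim-style costs, modulation 0.83/deg) with intra-individual and
  inter-individual summaries;
* **reliability** — fixation proportions inside a standardized 600×450 px
  facial AOI, and ICC(3,k) over the first 3/5/7 trials;
* **group statistics** — Shapiro–Wilk-gated t / Mann–Whitney comparisons
  with Cohen's d or rank-biserial r and bootstrap CIs;
* **classification** — subjects × (feature × trial) tables, exactly-10
  LASSO feature selection per fold, leave-one-subject-out CV over four
  model families (SVM, Extra-Trees, XGBoost, LightGBM), reporting
  accuracy, F1, AUROC and AUCPR;
* **synthetic cohorts** — a generator that simulates two-group 90 Hz gaze
  recordings with configurable effect sizes, blink/missing artifacts,
  subject idiosyncrasy and per-patient impairment profiles, since
  clinical gaze recordings are rarely shareable.

The model at the core of the statistics is simple and explicit: per trial
`t` of subject `s`, each feature `f` is an independent draw around a
subject mean, `x_fst = μ_f · g_group(f) · u_sf + ε`, where `g_group`
encodes the impaired group's multiplicative shift and `u_sf` the
subject's idiosyncrasy; group comparisons test `g_case(f) ≠ 1` and the
classifier learns the subject-level pattern across features and trials.

## Worked example

```python
import oculoscreen as oc

spec = oc.CohortSpec(n_subjects_per_group=(16, 23), n_trials=10, seed=1)
cohort = oc.simulate_cohort(spec)
kept = [c for c, qc in (oc.preprocess_trial(t) for t in cohort.trials) if qc.keep]
events = [(t.subject_id, t.trial_id, t.stimulus_id, oc.detect_events(t))
          for t in kept]
features = oc.cohort_features(events)
stats = oc.compare_feature_table(features, cohort.groups, oc.GROUP_CONTROL,
                                 oc.GROUP_CASE, oc.FEATURE_NAMES,
                                 unit="subject", n_boot=2000, seed=1)
print(stats[["feature", "test", "p_two_tailed", "effect_size"]].round(3))
```

prints (abridged; full table in `examples/02_group_comparison.py`):

```
                    feature          test  p_two_tailed  effect_size
     mean_saccade_velocity             t         0.002        1.057
    mean_saccade_amplitude             t         0.004        0.990
          inflection_count  mann-whitney         0.000       -0.924
    mean_fixation_duration  mann-whitney         0.000        0.908
            fixation_count  mann-whitney         0.000       -0.921
           shannon_entropy             t         0.899       -0.042
           scanpath_length  mann-whitney         0.000       -0.957
```

Read: the impaired cohort saccades more slowly and less far, changes
direction less often, fixates longer and less often, and covers a
shorter scanpath (9 of 11 features at p < 0.05 with large effect sizes;
Cohen's d is positive when controls score higher, rank-biserial r follows
r = 1 − 2U/(n₁n₂) on the control-group U), while gaze-dispersion entropy
does not differ — the impaired group explores less, not more chaotically.
`examples/` contains five short scripts, one per
capability (simulation & features, group stats, scanpath similarity,
reliability, classification); each prints its numbers with a sentence on
what they mean.

A thin CLI covers the file-based workflow:

```bash
oculoscreen simulate --config cohort.yaml --out gaze.csv --labels-out labels.json
oculoscreen run-all --gaze gaze.csv --labels labels.json --out results/
```

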