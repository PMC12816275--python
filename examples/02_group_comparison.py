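"""Compare oculomotor features between the two simulated cohorts.

Runs the normality-gated two-group tests (Shapiro-Wilk gate; t-test or
Mann-Whitney U) on subject-level feature means and prints which features
separate the groups, with effect sizes.
"""

import oculoscreen as oc

spec = oc.CohortSpec(n_subjects_per_group=(16, 23), n_trials=10, seed=1)
cohort = oc.simulate_cohort(spec)
kept = [c for c, qc in (oc.preprocess_trial(t) for t in cohort.trials) if qc.keep]
events = [(t.subject_id, t.trial_id, t.stimulus_id, oc.detect_events(t)) for t in kept]
features = oc.cohort_features(events)

stats = oc.compare_feature_table(
    features, cohort.groups, oc.GROUP_CONTROL, oc.GROUP_CASE,
    oc.FEATURE_NAMES, unit="subject", n_boot=2000, seed=1)

print("subject-level group comparison (control vs impaired):")
view = stats[["feature", "test", "p_two_tailed", "effect_size",
              "mean_a", "mean_b"]].round(3)
view.columns = ["feature", "test", "p", "effect", "control_mean", "case_mean"]
print(view.to_string(index=False))

sig = stats.loc[stats["p_two_tailed"] < 0.05, "feature"]
print(f"\n{len(sig)} of {len(stats)} features differ at p < 0.05 (two-tailed).")
print("The impaired group shows longer fixations, fewer fixations, smaller "
      "and slower saccades, fewer attended regions and a shorter, smaller "
      "scanpath; gaze-dispersion entropy is expected NOT to differ.")
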