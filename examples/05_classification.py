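"""Subject-level classification with LASSO selection and LOOCV.

Builds the wide subjects x (feature, trial) table, selects 10 columns per
training fold by L1-penalised logistic regression, and evaluates a
support-vector machine by leave-one-subject-out cross-validation on each
feature family and on all features combined (swap in "extra_trees",
"xgboost" or "lightgbm" for the other model families).
"""

import oculoscreen as oc

spec = oc.CohortSpec(n_subjects_per_group=(16, 23), n_trials=10, seed=7)
cohort = oc.simulate_cohort(spec)
kept = [c for c, qc in (oc.preprocess_trial(t) for t in cohort.trials) if qc.keep]
events = [(t.subject_id, t.trial_id, t.stimulus_id, oc.detect_events(t)) for t in kept]
features = oc.cohort_features(events)

reports = oc.evaluate_feature_sets(
    features, cohort.groups, case_label=oc.GROUP_CASE, n_trials=10,
    model_families=("svm",),
    feature_sets=("saccadic", "fixation", "scanpath", "multi_type"), seed=7)

print(f"{'feature set':12s} {'model':12s} {'acc%':>6s} {'F1%':>6s} "
      f"{'AUROC':>6s} {'AUCPR':>6s}")
for r in reports:
    print(f"{r.feature_set:12s} {r.model:12s} {r.accuracy:6.1f} {r.f1:6.1f} "
          f"{r.auroc:6.3f} {r.aucpr:6.3f}")

print("\nEach row pools one prediction per held-out subject (39 folds). "
      "With the default simulated effect sizes every feature family "
      "separates the cohorts well; as effects weaken, the combined "
      "multi_type set stays at or above the best single family because "
      "the impairment touches several aspects of oculomotor behaviour "
      "at once.")
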