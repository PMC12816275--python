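"""Feature table construction, exactly-k selection, leakage-free LOOCV."""

import numpy as np
import pandas as pd
import pytest
from sklearn.preprocessing import StandardScaler

from oculoscreen import (FeatureTable, build_feature_table, lasso_select,
                         loocv_evaluate)
from oculoscreen.features import FEATURE_NAMES


def tidy_features(n_subjects=6, n_trials=3, seed=0, missing=()):
    """Synthetic tidy per-trial feature frame with group labels."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        for t in range(n_trials):
            if (s, t) in missing:
                continue
            row = {"subject_id": f"s{s:02d}", "trial_id": f"t{t:02d}",
                   "stimulus_id": f"stim{t:02d}"}
            row.update({name: rng.standard_normal() for name in FEATURE_NAMES})
            rows.append(row)
    groups = {f"s{s:02d}": ("case" if s >= n_subjects // 2 else "control")
              for s in range(n_subjects)}
    return pd.DataFrame(rows), groups


def separable_table(n_per_class=8, n_cols=12, margin=10.0, seed=0) -> FeatureTable:
    """Half the columns carry a huge class shift: separable in any subset."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((2 * n_per_class, n_cols))
    y = np.repeat([0, 1], n_per_class)
    X[:, :n_cols // 2] += y[:, None] * margin
    frame = pd.DataFrame(X, index=[f"s{i}" for i in range(2 * n_per_class)],
                         columns=[f"c{i}" for i in range(n_cols)])
    return FeatureTable(X=frame, y=y, missing_mask=frame.isna())


def test_feature_table_shape_and_order():
    feats, groups = tidy_features(n_subjects=2, n_trials=3)
    table = build_feature_table(feats, groups, "case", n_trials=3)
    assert table.X.shape == (2, 33)
    assert list(table.X.columns[:3]) == [
        "mean_saccade_velocity__t01", "mean_saccade_velocity__t02",
        "mean_saccade_velocity__t03"]
    # permuting input rows yields the identical table
    shuffled = feats.sample(frac=1.0, random_state=1)
    table2 = build_feature_table(shuffled, groups, "case", n_trials=3)
    pd.testing.assert_frame_equal(table.X, table2.X)
    np.testing.assert_array_equal(table.y, table2.y)


def test_feature_table_within_subject_median_imputation():
    feats, groups = tidy_features(n_subjects=4, n_trials=4, missing={(1, 3)})
    table = build_feature_table(feats, groups, "case", n_trials=4)
    sid = "s01"
    for name in FEATURE_NAMES:
        own = feats.loc[feats["subject_id"] == sid, name]
        assert table.X.loc[sid, f"{name}__t04"] == pytest.approx(own.median())
    assert table.missing_mask.loc[sid, f"{FEATURE_NAMES[0]}__t04"]


def test_feature_table_excludes_empty_subject():
    feats, groups = tidy_features(n_subjects=3, n_trials=2,
                                  missing={(2, 0), (2, 1)})
    table = build_feature_table(feats, groups, "case", n_trials=2)
    assert "s02" not in table.X.index


def test_feature_table_family_subsets():
    feats, groups = tidy_features(n_subjects=2, n_trials=2)
    for fam, width in (("saccadic", 10), ("fixation", 6), ("scanpath", 6)):
        assert build_feature_table(feats, groups, "case", 2, fam).X.shape == (2, width)
    with pytest.raises(ValueError):
        build_feature_table(feats, groups, "case", 2, "pupil")


def test_lasso_select_few_columns_returns_all():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((30, 5))
    y = rng.integers(0, 2, 30)
    idx, exact = lasso_select(X, y, k=10)
    assert list(idx) == [0, 1, 2, 3, 4]
    assert not exact


def test_lasso_select_exactly_k_and_deterministic():
    rng = np.random.default_rng(1)
    X = StandardScaler().fit_transform(rng.standard_normal((60, 40)))
    y = (X[:, :3].sum(axis=1) + 0.5 * rng.standard_normal(60) > 0).astype(int)
    idx1, exact1 = lasso_select(X, y, k=10, seed=5)
    idx2, _ = lasso_select(X, y, k=10, seed=5)
    assert exact1 and len(idx1) == 10
    np.testing.assert_array_equal(idx1, idx2)


def test_lasso_select_finds_informative_column():
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((40, 31))
        y = np.repeat([0, 1], 20)
        X[:, 7] += y * 4.0  # the informative column
        Xs = StandardScaler().fit_transform(X)
        idx, _ = lasso_select(Xs, y, k=10, seed=seed)
        hits += 7 in idx
    assert hits >= 9


def test_loocv_separable_is_perfect():
    table = separable_table()
    report = loocv_evaluate(table, "svm", k=10, seed=0)
    assert report.accuracy == 100.0
    assert report.auroc == 1.0
    assert len(report.y_true) == 16  # one fold per subject


def test_loocv_fold_models_ignore_held_out_subject():
    """Leakage guard: corrupting subject i's features must not change what
    fold i selects or how it scales (its model never sees subject i)."""
    table = separable_table(n_per_class=6, n_cols=14, seed=2)
    base = loocv_evaluate(table, "svm", k=5, seed=0)
    corrupted = FeatureTable(X=table.X.copy(), y=table.y,
                             missing_mask=table.missing_mask)
    corrupted.X.iloc[3] = 1e6
    after = loocv_evaluate(corrupted, "svm", k=5, seed=0)
    assert base.selected_indices[3] == after.selected_indices[3]


def test_loocv_global_selection_differs_from_per_fold():
    table = separable_table(n_per_class=6, n_cols=14, seed=3)
    per_fold = loocv_evaluate(table, "svm", k=5, seed=0)
    global_sel = loocv_evaluate(table, "svm", k=5, seed=0, global_selection=True)
    # the leaky variant uses one fixed selection across folds
    assert len(set(global_sel.selected_indices)) == 1
    assert len(per_fold.y_true) == len(global_sel.y_true)


def test_loocv_requires_two_per_class():
    table = separable_table(n_per_class=6)
    table.y = np.array([0] * 11 + [1])
    with pytest.raises(ValueError):
        loocv_evaluate(table, "svm")


@pytest.mark.parametrize("family", ["svm", "extra_trees", "xgboost", "lightgbm"])
def test_all_model_families_run_and_are_reproducible(family):
    table = separable_table(n_per_class=5, n_cols=8, margin=6.0, seed=4)
    r1 = loocv_evaluate(table, family, k=5, seed=1)
    r2 = loocv_evaluate(table, family, k=5, seed=1)
    assert r1.accuracy == r2.accuracy
    np.testing.assert_allclose(r1.scores, r2.scores)
    assert r1.accuracy >= 90.0  # wide margin: every family should separate
    assert 0.0 <= r1.aucpr <= 1.0


def test_unknown_model_family_rejected():
    from oculoscreen.ml_pipeline import make_model
    with pytest.raises(ValueError):
        make_model("perceptron")


def test_accuracy_consistent_with_stored_predictions():
    table = separable_table(n_per_class=6, n_cols=10, margin=2.0, seed=5)
    report = loocv_evaluate(table, "extra_trees", k=5, seed=0)
    recomputed = 100.0 * np.mean(report.y_true == report.y_pred)
    assert report.accuracy == pytest.approx(recomputed)


def test_selection_count_never_exceeds_k():
    table = separable_table(n_per_class=7, n_cols=20, margin=3.0, seed=7)
    report = loocv_evaluate(table, "svm", k=6, seed=0)
    assert all(c <= 6 for c in report.selected_counts)
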