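"""Normative model: folds, determinism, out-of-fold hygiene, metrics."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import tapage as tp
from tests.conftest import SMALL_HP, SMALL_SEED


def _records(ages):
    return [
        tp.SubjectRecord(
            subject_id=f"s{i:03d}",
            chronological_age=float(a),
            gender_code=0,
            screen_size=5.0,
            cohort_label="healthy",
            recording_days=30,
        )
        for i, a in enumerate(ages)
    ]


# ------------------------------------------------------------------- folds


def test_folds_balanced_and_deterministic():
    recs = _records(np.linspace(20, 80, 100))
    f1 = tp.make_folds(recs, k=10, seed=4)
    f2 = tp.make_folds(recs, k=10, seed=4)
    assert f1 == f2
    sizes = np.bincount(list(f1.values()), minlength=10)
    assert np.all(sizes == 10)


def test_folds_are_age_stratified():
    rng = np.random.default_rng(0)
    recs = _records(rng.uniform(16, 86, 300))
    folds = tp.make_folds(recs, k=10, seed=1)
    ages = {r.subject_id: r.chronological_age for r in recs}
    overall = np.mean(list(ages.values()))
    for k in range(10):
        fold_ages = [ages[s] for s, f in folds.items() if f == k]
        assert abs(np.mean(fold_ages) - overall) < 3.0


def test_too_many_folds_rejected():
    with pytest.raises(ValueError):
        tp.make_folds(_records([30, 40]), k=10, seed=0)


# ---------------------------------------------------------------- training


def test_training_is_deterministic(small_features):
    folds = tp.make_folds(small_features, k=10, seed=SMALL_SEED)
    b1 = tp.train_normative(small_features, folds, SMALL_HP, seed=SMALL_SEED)
    b2 = tp.train_normative(small_features, folds, SMALL_HP, seed=SMALL_SEED)
    p1 = tp.predict_out_of_fold(b1, small_features)
    p2 = tp.predict_out_of_fold(b2, small_features)
    assert np.array_equal(p1["predicted_age"], p2["predicted_age"])


def test_constant_age_cohort_predicts_that_age(small_features):
    table = tp.FeatureTable(
        X=small_features.X,
        subject_ids=small_features.subject_ids,
        ages=np.full(len(small_features), 40.0),
        cohort_labels=small_features.cohort_labels,
        window_days=small_features.window_days,
        feature_names=small_features.feature_names,
    )
    folds = tp.make_folds(table, k=10, seed=0)
    bundle = tp.train_normative(table, folds, SMALL_HP, seed=0)
    oof = tp.predict_out_of_fold(bundle, table)
    assert np.allclose(oof["predicted_age"], 40.0, atol=0.5)


def test_nan_feature_names_subject_and_column(small_features):
    X = small_features.X.copy()
    X[3, 17] = np.nan
    table = tp.FeatureTable(
        X=X,
        subject_ids=small_features.subject_ids,
        ages=small_features.ages,
        cohort_labels=small_features.cohort_labels,
        window_days=small_features.window_days,
        feature_names=small_features.feature_names,
    )
    folds = tp.make_folds(table, k=10, seed=0)
    sid = small_features.subject_ids[3]
    col = small_features.feature_names[17]
    with pytest.raises(ValueError, match=f"{sid}.*{col}"):
        tp.train_normative(table, folds, SMALL_HP, seed=0)


def test_hyperparameter_defaults_are_the_frozen_configuration():
    hp = tp.ModelHyperparams()
    assert (hp.max_depth, hp.n_trees) == (9, 567)
    assert hp.learning_rate == pytest.approx(1e-2)
    assert hp.min_child_weight == 8.0
    assert hp.l1_alpha == pytest.approx(1e-3)
    assert hp.col_subsample == 1.0 and hp.row_subsample == 1.0


# ------------------------------------------------------------- predictions


def test_out_of_fold_covers_each_subject_once(small_oof, small_features):
    assert len(small_oof) == len(small_features)
    assert small_oof["subject_id"].is_unique
    err = small_oof["predicted_age"] - small_oof["chronological_age"]
    assert np.allclose(small_oof["error"], err)


def test_out_of_fold_hygiene(small_bundle, small_oof):
    # the model that predicts a subject is the one assigned to its fold
    for row in small_oof.itertuples():
        assert small_bundle.fold_assignment[row.subject_id] == row.model_index


def test_predicted_age_tracks_true_age(small_oof):
    rho = spearmanr(small_oof["predicted_age"], small_oof["chronological_age"]).statistic
    assert rho > 0.5


def test_predict_cohort_shape_and_window_discipline(small_bundle, small_features):
    table = tp.predict_cohort(small_bundle, small_features)
    assert len(table) == 10 * len(small_features)
    assert set(table["model_index"]) == set(range(10))
    wrong_window = tp.FeatureTable(
        X=small_features.X,
        subject_ids=small_features.subject_ids,
        ages=small_features.ages,
        cohort_labels=small_features.cohort_labels,
        window_days=90,
        feature_names=small_features.feature_names,
    )
    with pytest.raises(ValueError, match="window"):
        tp.predict_cohort(small_bundle, wrong_window)


def test_null_input_prediction_is_deterministic(small_bundle):
    m1, per1 = tp.null_input_prediction(small_bundle)
    m2, per2 = tp.null_input_prediction(small_bundle)
    assert m1 == m2
    assert np.array_equal(per1, per2)
    assert per1.shape == (10,)


def test_bundle_roundtrip(tmp_path, small_bundle, small_features):
    tp.save_bundle(small_bundle, tmp_path / "bundle")
    loaded = tp.load_bundle(tmp_path / "bundle")
    assert loaded.fold_assignment == small_bundle.fold_assignment
    assert loaded.hyperparams == small_bundle.hyperparams
    assert loaded.training_window_days == small_bundle.training_window_days
    a = tp.predict_out_of_fold(small_bundle, small_features)
    b = tp.predict_out_of_fold(loaded, small_features)
    assert np.allclose(a["predicted_age"], b["predicted_age"], atol=1e-6)


# ----------------------------------------------------------------- metrics


def _table(real, pred):
    real = np.asarray(real, dtype=float)
    pred = np.asarray(pred, dtype=float)
    return pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(real.size)],
            "chronological_age": real,
            "predicted_age": pred,
            "error": pred - real,
            "model_index": 0,
            "cohort_label": "healthy",
        }
    )


def test_metrics_perfect_prediction():
    m = tp.performance_metrics(_table([30, 50, 70], [30, 50, 70]))
    assert (m["ME"], m["MAE"], m["R2"]) == (0.0, 0.0, 1.0)


def test_metrics_toy_arithmetic():
    m = tp.performance_metrics(_table([48, 62], [50, 60]))
    assert m["ME"] == pytest.approx(0.0)
    assert m["MAE"] == pytest.approx(2.0)


def test_squared_correlation_ignores_sign():
    # the documented caveat of the squared-correlation convention
    m = tp.performance_metrics(_table([20, 40, 60], [60, 40, 20]))
    assert m["R2"] == pytest.approx(1.0)
    assert m["R2_cod"] < 0  # the coefficient of determination does not


def test_constant_predictions_warn_and_report_nan():
    with pytest.warns(UserWarning, match="R2 undefined"):
        m = tp.performance_metrics(_table([30, 50], [40, 40]))
    assert np.isnan(m["R2"])


# ---------------------------------------------------------------- duration


def test_duration_full_window_matches_baseline(small_bundle, small_features, small_cohort):
    _, streams, records = small_cohort
    streams, records = tp.apply_inclusion_filter(records, streams, min_days=7)
    curve = tp.duration_sensitivity(
        small_bundle, streams, records, test_days=[small_features.window_days], seed=0
    )
    baseline = tp.performance_metrics(tp.predict_out_of_fold(small_bundle, small_features))
    assert curve["mae"].iloc[0] == pytest.approx(baseline["MAE"], abs=1e-9)
    assert curve["ci_low"].iloc[0] <= curve["mae"].iloc[0] <= curve["ci_high"].iloc[0]
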