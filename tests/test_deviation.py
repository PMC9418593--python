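"""Deviation analysis: patient medians, age-matched null, tests, robust fit."""

import numpy as np
import pandas as pd
import pytest

import tapage as tp


def _patient_table(errors_by_model, ages=None):
    """10 models x n patients prediction table with given per-model errors."""
    rows = []
    n = len(errors_by_model[0])
    ages = ages if ages is not None else np.linspace(30, 70, n)
    for m, errs in enumerate(errors_by_model):
        for i, e in enumerate(errs):
            rows.append(
                {
                    "subject_id": f"p{i}",
                    "chronological_age": ages[i],
                    "predicted_age": ages[i] + e,
                    "error": e,
                    "model_index": m,
                    "cohort_label": "patient",
                }
            )
    return pd.DataFrame(rows)


def _healthy_oof(ages, errors):
    ages = np.asarray(ages, dtype=float)
    errors = np.asarray(errors, dtype=float)
    return pd.DataFrame(
        {
            "subject_id": [f"h{i}" for i in range(ages.size)],
            "chronological_age": ages,
            "predicted_age": ages + errors,
            "error": errors,
            "model_index": 0,
            "cohort_label": "healthy",
        }
    )


# ------------------------------------------------------------ patient_errors


def test_exact_predictions_give_zero_medians():
    table = _patient_table([np.zeros(5)] * 10)
    assert np.array_equal(tp.patient_errors(table), np.zeros(10))


def test_constant_error_propagates_to_all_medians():
    table = _patient_table([np.full(5, 5.0)] * 10)
    assert np.array_equal(tp.patient_errors(table), np.full(10, 5.0))


def test_medians_invariant_to_patient_order():
    rng = np.random.default_rng(0)
    errs = [rng.normal(0, 3, 9) for _ in range(10)]
    table = _patient_table(errs)
    shuffled = table.sample(frac=1, random_state=1).reset_index(drop=True)
    assert np.allclose(tp.patient_errors(table), tp.patient_errors(shuffled))


def test_single_patient_rejected():
    table = _patient_table([np.zeros(1)] * 10)
    with pytest.raises(ValueError, match="2 patients"):
        tp.patient_errors(table)


# ------------------------------------------------------------ bootstrap_null


def test_null_medians_respect_age_matching():
    # healthy error == age makes the matched median age-readable
    ages = np.arange(20, 81, dtype=float)
    oof = _healthy_oof(ages, ages)
    null = tp.bootstrap_null(oof, np.array([20.0, 50.0, 80.0]), n_iter=200, seed=1)
    assert null.shape == (200,)
    assert np.all(null >= 48.0) and np.all(null <= 52.0)  # median = the age-50 match


def test_no_candidate_within_tolerance_is_an_error():
    oof = _healthy_oof([30.0, 31.0, 60.0], [0, 0, 0])
    with pytest.raises(ValueError, match="45.0"):
        tp.bootstrap_null(oof, np.array([45.0]), n_iter=10, seed=0)


def test_pool_too_thin_for_without_replacement():
    oof = _healthy_oof([50.0, 70.0], [0, 0])
    with pytest.raises(ValueError, match="too thin"):
        tp.bootstrap_null(oof, np.array([50.0, 50.5]), n_iter=10, seed=0)


def test_bootstrap_is_deterministic_given_seed():
    rng = np.random.default_rng(3)
    oof = _healthy_oof(rng.uniform(20, 80, 100), rng.normal(0, 5, 100))
    patients = np.array([25.0, 40.0, 55.0, 70.0])
    a = tp.bootstrap_null(oof, patients, n_iter=50, seed=9)
    b = tp.bootstrap_null(oof, patients, n_iter=50, seed=9)
    assert np.array_equal(a, b)


# ------------------------------------------------------ compare_distributions


def test_identical_distributions_are_not_separated():
    vals = np.array([1.0, 2.0, 3.0, 4.0])
    t, p = tp.compare_distributions(vals, vals)
    assert t == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0, abs=1e-12)


def test_large_shift_separates_distributions():
    rng = np.random.default_rng(0)
    a = rng.normal(10.0, 0.01, 10)
    b = rng.normal(0.0, 0.01, 1000)
    t, p = tp.compare_distributions(a, b)
    assert t > 50
    assert p < 1e-6


def test_welch_t_matches_hand_computation():
    # frozen from the textbook formula: t = (2-5)/sqrt(1/3 + (20/3)/4)
    t, p = tp.compare_distributions([1.0, 2.0, 3.0], [2.0, 4.0, 6.0, 8.0])
    assert t == pytest.approx(-2.1213203435596424, abs=1e-12)
    assert p == pytest.approx(0.09991286431180087, abs=1e-10)


def test_zero_variance_everywhere_is_an_error():
    with pytest.raises(ValueError, match="variance"):
        tp.compare_distributions([1.0, 1.0], [1.0, 1.0, 1.0])


# ------------------------------------------------------ robust_age_regression


def test_perfect_line_recovered():
    real = np.linspace(20, 80, 10)
    fit = tp.robust_age_regression(real, real)
    assert fit.slope == pytest.approx(1.0)
    assert fit.intercept == pytest.approx(0.0, abs=1e-9)
    assert fit.r2 == pytest.approx(1.0)
    assert fit.df == 8


def test_huber_fit_resists_gross_outlier():
    rng = np.random.default_rng(5)
    real = np.linspace(20, 80, 20)
    pred = real + rng.normal(0, 0.5, 20)
    pred[3] += 80.0  # one gross outlier
    robust = tp.robust_age_regression(pred, real)
    ols_slope = np.polyfit(real, pred, 1)[0]
    assert abs(robust.slope - 1.0) < 0.05
    assert abs(ols_slope - 1.0) > 2 * abs(robust.slope - 1.0)


def test_degrees_of_freedom_are_n_minus_two():
    rng = np.random.default_rng(1)
    real = np.linspace(22, 83, 41)
    pred = 0.5 * real + 25 + rng.normal(0, 5, 41)
    fit = tp.robust_age_regression(pred, real)
    assert fit.df == 39
    assert 0 < fit.p_value < 1


def test_constant_real_ages_rejected():
    with pytest.raises(ValueError, match="constant"):
        tp.robust_age_regression(np.array([30.0, 40.0, 50.0]), np.array([50.0, 50.0, 50.0]))


# ----------------------------------------------------------- analyze_deviation


def test_full_report_structure_and_sign_convention():
    rng = np.random.default_rng(2)
    h_ages = rng.uniform(20, 80, 120)
    oof = _healthy_oof(h_ages, rng.normal(0, 4, 120))
    n_pat = 15
    ages = rng.uniform(30, 70, n_pat)
    shift = 6.0
    errs = [shift + rng.normal(0, 2, n_pat) for _ in range(10)]
    table = _patient_table(errs, ages=ages)
    report = tp.analyze_deviation(table, oof, window_days=90, n_iter=300, seed=4)
    assert report.patient_model_medians.shape == (10,)
    assert report.null_medians.shape == (300,)
    assert report.gap_years == pytest.approx(shift, abs=2.0)
    assert report.t_statistic > 0  # advanced age ⇒ positive separation
    d = report.to_dict()
    assert d["n_null_iterations"] == 300
    assert "slope" in d["robust_fit"]
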