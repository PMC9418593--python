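"""Deviation of a disease cohort from the healthy-aging norm.

Quantifies "advanced behavioral age": the trained normative bundle predicts
ages for a patient cohort (ten predictions per patient, one per fold
model), and the typical (median) signed error per model is contrasted with
a bootstrap null distribution built from age-matched healthy subjects'
out-of-fold errors.  Per iteration, each patient is matched to a distinct
healthy subject within a tolerance (default +/- 2 years) sampled without
replacement, and the median of the matched errors is recorded; over many
iterations this yields the null distribution of typical errors under
healthy aging.  The two sets of medians are compared with a two-sample
t-test (Welch by default), and a per-patient robust linear regression
(Huber M-estimator) relates predicted to real age.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)


def patient_errors(patient_table: pd.DataFrame) -> np.ndarray:
    """Median signed error per fold model (one value per model)."""
    n_subjects = patient_table["subject_id"].nunique()
    if n_subjects < 2:
        raise ValueError("need at least 2 patients")
    medians = patient_table.groupby("model_index")["error"].median()
    return medians.sort_index().to_numpy()


def bootstrap_null(
    healthy_oof: pd.DataFrame,
    patient_ages: np.ndarray,
    n_iter: int = 10_000,
    matching_tolerance_years: float = 2.0,
    seed: int = 0,
) -> np.ndarray:
    """Null distribution of median errors from age-matched healthy subjects.

    For each iteration, every patient is paired with a distinct healthy
    subject whose age lies within the matching tolerance (uniform sampling
    without replacement within the iteration); the median of the matched
    out-of-fold errors is recorded.

    Raises ``ValueError`` if some patient has no healthy subject within
    tolerance, or if the pool is too thin for without-replacement sampling.
    """
    patient_ages = np.asarray(patient_ages, dtype=float)
    h_ages = healthy_oof["chronological_age"].to_numpy(dtype=float)
    h_err = healthy_oof["error"].to_numpy(dtype=float)

    candidates: list[np.ndarray] = []
    for a in patient_ages:
        pool = np.flatnonzero(np.abs(h_ages - a) <= matching_tolerance_years)
        if pool.size == 0:
            raise ValueError(f"no healthy subject within {matching_tolerance_years} years of age {a:.1f}")
        candidates.append(pool)

    # scarcest pools pick first so without-replacement sampling cannot strand
    order = np.argsort([c.size for c in candidates])
    rng = np.random.default_rng(seed)
    n_h = h_ages.size
    medians = np.empty(n_iter)
    for it in range(n_iter):
        used = np.zeros(n_h, dtype=bool)
        picked = np.empty(patient_ages.size, dtype=np.intp)
        for j in order:
            pool = candidates[j]
            free = pool[~used[pool]]
            if free.size == 0:
                raise ValueError(
                    "healthy pool too thin for without-replacement age matching "
                    f"(patient age {patient_ages[j]:.1f})"
                )
            choice = free[rng.integers(0, free.size)]
            used[choice] = True
            picked[j] = choice
        medians[it] = np.median(h_err[picked])
    return medians


def compare_distributions(
    patient_model_medians: np.ndarray,
    null_medians: np.ndarray,
    equal_var: bool = False,
) -> tuple[float, float]:
    """Two-sample t-test between patient and null median errors.

    Welch's unequal-variance form by default; set ``equal_var=True`` for
    the pooled-variance variant.
    """
    a = np.asarray(patient_model_medians, dtype=float)
    b = np.asarray(null_medians, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if np.std(a) == 0 and np.std(b) == 0:
        raise ValueError("zero variance in both samples; t-test undefined")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


@dataclass(frozen=True)
class RobustFit:
    """Huber robust linear fit of predicted on real age."""

    slope: float
    intercept: float
    r2: float
    t_stat: float
    p_value: float
    df: int


def robust_age_regression(predicted: np.ndarray, real_ages: np.ndarray) -> RobustFit:
    """Iteratively reweighted least squares with Huber weights (c = 1.345).

    The slope t statistic uses n - 2 degrees of freedom; R2 is the squared
    Pearson correlation between predicted and real age, matching the
    normative model's convention.
    """
    predicted = np.asarray(predicted, dtype=float)
    real = np.asarray(real_ages, dtype=float)
    if predicted.size < 3:
        raise ValueError("need at least 3 patients")
    if np.std(real) == 0:
        raise ValueError("real ages are constant; regression undefined")
    df = predicted.size - 2
    X = sm.add_constant(real)

    ols = sm.OLS(predicted, X).fit()
    if np.max(np.abs(ols.resid)) < 1e-9 * max(1.0, float(np.std(predicted))):
        # perfect linear data: the robust scale estimate degenerates
        return RobustFit(
            slope=float(ols.params[1]),
            intercept=float(ols.params[0]),
            r2=1.0,
            t_stat=float("inf"),
            p_value=0.0,
            df=df,
        )

    rlm = sm.RLM(predicted, X, M=sm.robust.norms.HuberT(t=1.345)).fit()
    t_stat = float(rlm.params[1] / rlm.bse[1])
    p = float(2.0 * stats.t.sf(abs(t_stat), df))
    r2 = float(np.corrcoef(predicted, real)[0, 1] ** 2) if np.std(predicted) > 0 else float("nan")
    return RobustFit(
        slope=float(rlm.params[1]),
        intercept=float(rlm.params[0]),
        r2=r2,
        t_stat=t_stat,
        p_value=p,
        df=df,
    )


@dataclass
class DeviationReport:
    """Headline output of the disease-versus-norm analysis (years)."""

    patient_model_medians: np.ndarray
    null_medians: np.ndarray
    t_statistic: float
    p_value: float
    empirical_p: float
    patient_mae: float
    gap_years: float
    robust_fit: RobustFit
    window_days: int
    matching_tolerance_years: float

    def to_dict(self, include_null: bool = False) -> dict:
        out = {
            "patient_model_medians": [float(v) for v in self.patient_model_medians],
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "empirical_p": self.empirical_p,
            "patient_mae": self.patient_mae,
            "gap_years": self.gap_years,
            "null_median_mean": float(np.mean(self.null_medians)),
            "null_median_sd": float(np.std(self.null_medians)),
            "n_null_iterations": int(self.null_medians.size),
            "robust_fit": asdict(self.robust_fit),
            "window_days": self.window_days,
            "matching_tolerance_years": self.matching_tolerance_years,
        }
        if include_null:
            out["null_medians"] = [float(v) for v in self.null_medians]
        return out

    def to_json(self, path: str | Path, include_null: bool = False) -> None:
        Path(path).write_text(json.dumps(self.to_dict(include_null), indent=2))


def analyze_deviation(
    patient_table: pd.DataFrame,
    healthy_oof: pd.DataFrame,
    window_days: int,
    n_iter: int = 10_000,
    matching_tolerance_years: float = 2.0,
    seed: int = 0,
    patient_summary: str = "median",
) -> DeviationReport:
    """Full deviation analysis of one patient cohort against the norm.

    ``patient_table`` must come from :func:`tapage.model.predict_cohort`
    (ten rows per patient).  ``patient_summary`` selects how the ten model
    outputs are collapsed to one predicted age per patient for the robust
    regression ("median" or "mean").
    """
    medians = patient_errors(patient_table)
    per_patient = patient_table.groupby("subject_id").agg(
        predicted_age=("predicted_age", patient_summary),
        chronological_age=("chronological_age", "first"),
    )
    null = bootstrap_null(
        healthy_oof,
        per_patient["chronological_age"].to_numpy(),
        n_iter=n_iter,
        matching_tolerance_years=matching_tolerance_years,
        seed=seed,
    )
    t, p = compare_distributions(medians, null)
    # calibrated alternative to the t-test: where the typical patient error
    # falls within the bootstrap null (two-sided empirical p); unlike the
    # t-test this carries patient-cohort sampling variability in the null
    frac = float(np.mean(null >= np.mean(medians)))
    empirical_p = float(min(1.0, 2.0 * min(frac, 1.0 - frac) + 1.0 / null.size))
    fit = robust_age_regression(
        per_patient["predicted_age"].to_numpy(),
        per_patient["chronological_age"].to_numpy(),
    )
    return DeviationReport(
        patient_model_medians=medians,
        null_medians=null,
        t_statistic=t,
        p_value=p,
        empirical_p=empirical_p,
        patient_mae=float(np.abs(patient_table["error"]).mean()),
        gap_years=float(np.mean(medians) - np.mean(null)),
        robust_fit=fit,
        window_days=window_days,
        matching_tolerance_years=matching_tolerance_years,
    )
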