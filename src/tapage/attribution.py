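"""Shapley attribution of behavioral-age predictions.

Each prediction is decomposed into additive per-feature contributions
(Shapley values of the tree ensemble's cover-weighted conditional
expectation game), computed exactly in double precision by the tree-path
algorithm in :mod:`tapage._treeshap`.  For every subject, base value + sum
of contributions equals the prediction to near machine precision.  Population maps average the positive and the negative parts
of the 2500 JID-cell contributions separately, which shows *where* in the
interval plane behavior pushes age estimates up (typically slow intervals)
or down (fast consecutive intervals in the young).

Healthy subjects are attributed by their out-of-fold model; disease
cohorts by the average over all ten fold models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xgboost as xgb

from . import _treeshap
from .features import COVARIATE_NAMES, FeatureTable
from .model import NormativeModelBundle, _check_alignment


@dataclass
class AttributionMap:
    """Per-subject additive attributions (years) plus base values."""

    subject_ids: list[str]
    values: np.ndarray  # (n_subjects, n_features)
    base_values: np.ndarray  # (n_subjects,)
    predictions: np.ndarray  # (n_subjects,)
    feature_names: list[str]


def _contribs(model: xgb.Booster, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    values, base, pred = _treeshap.shap_values(model, X)
    return values, np.full(X.shape[0], base), pred


def attribute(
    bundle: NormativeModelBundle,
    features: FeatureTable,
    out_of_fold: bool | None = None,
    allow_window_mismatch: bool = False,
) -> AttributionMap:
    """Exact tree-path Shapley attributions for every subject.

    ``out_of_fold=True`` attributes each subject with its held-out fold
    model (requires fold assignments for all subjects); ``False`` averages
    contributions over all fold models.  ``None`` picks out-of-fold when
    every subject has a fold assignment.
    """
    _check_alignment(bundle, features, allow_window_mismatch)
    if out_of_fold is None:
        out_of_fold = all(s in bundle.fold_assignment for s in features.subject_ids)

    n, m = features.X.shape
    if out_of_fold:
        unknown = [s for s in features.subject_ids if s not in bundle.fold_assignment]
        if unknown:
            raise ValueError(f"subjects without fold assignment: {unknown[:5]}")
        fold_ids = np.array([bundle.fold_assignment[s] for s in features.subject_ids])
        values = np.empty((n, m))
        base = np.empty(n)
        pred = np.empty(n)
        for i, model in enumerate(bundle.fold_models):
            mask = fold_ids == i
            if mask.any():
                values[mask], base[mask], pred[mask] = _contribs(model, features.X[mask])
    else:
        values = np.zeros((n, m))
        base = np.zeros(n)
        pred = np.zeros(n)
        for model in bundle.fold_models:
            v, b, p = _contribs(model, features.X)
            values += v
            base += b
            pred += p
        k = bundle.n_folds
        values /= k
        base /= k
        pred /= k
    return AttributionMap(
        subject_ids=list(features.subject_ids),
        values=values,
        base_values=base,
        predictions=pred,
        feature_names=list(features.feature_names),
    )


@dataclass
class PopulationAttribution:
    """Population-mean positive/negative attribution maps on the JID plane."""

    positive: np.ndarray  # (n_bins, n_bins), elementwise >= 0
    negative: np.ndarray  # (n_bins, n_bins), elementwise <= 0
    covariate_summary: pd.DataFrame


def aggregate_population(amap: AttributionMap) -> PopulationAttribution:
    """Average the positive and negative parts of the attributions.

    Per JID cell: mean over subjects of max(attr, 0) and of min(attr, 0),
    so positive + negative equals the plain mean attribution map.  The four
    covariates are summarized in a separate table.
    """
    n_cov = len(COVARIATE_NAMES)
    n_jid = amap.values.shape[1] - n_cov
    n_bins = int(round(np.sqrt(n_jid)))
    jid = amap.values[:, :n_jid].reshape(-1, n_bins, n_bins)
    positive = np.maximum(jid, 0.0).mean(axis=0)
    negative = np.minimum(jid, 0.0).mean(axis=0)
    cov = amap.values[:, n_jid:]
    covariate_summary = pd.DataFrame(
        {
            "feature": amap.feature_names[n_jid:],
            "mean_positive": np.maximum(cov, 0.0).mean(axis=0),
            "mean_negative": np.minimum(cov, 0.0).mean(axis=0),
            "mean_abs": np.abs(cov).mean(axis=0),
        }
    )
    return PopulationAttribution(positive, negative, covariate_summary)


def plot_attribution_maps(
    pop: PopulationAttribution,
    grid_centers: np.ndarray,
    path: str,
    title: str = "Population attribution",
) -> None:
    """Render the positive (red) and negative (blue) maps side by side."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    for ax, mat, cmap, label in (
        (axes[0], pop.positive, "Reds", "positive (ages up)"),
        (axes[1], -pop.negative, "Blues", "negative (ages down)"),
    ):
        im = ax.pcolormesh(grid_centers, grid_centers, mat.T, cmap=cmap, shading="nearest")
        ax.set_xlabel("log10 ITI(k) [ms]")
        ax.set_title(label)
        fig.colorbar(im, ax=ax, label="|Shapley| (years)")
    axes[0].set_ylabel("log10 ITI(k+1) [ms]")
    fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
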