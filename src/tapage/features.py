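"""Joint interval distribution (JID) features.

The JID is a 50x50 probability mass over consecutive log10 inter-touch
intervals: each pair (ITI_k, ITI_{k+1}) is log10-transformed and smoothed
with an isotropic Gaussian kernel (bandwidth 0.1 log10-ms units) evaluated
at 50 equally spaced grid centers per axis spanning log10-ms [0.5, 5]
(about 3 ms to 28 h).  Cell values are renormalized to sum to one, so the
grid is a probability mass function over next-interval dynamics: fast
typing bursts, slow deliberate interactions, and transitions between them
occupy distinct regions of the plane.

The full per-subject feature vector has 2504 entries: the 2500 JID cells in
row-major order (ITI_k major), then the gender code, the Shannon entropy of
the JID in bits, log10 of the median daily interaction count, and the
screen size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ITIPairSet
from .synthetic import SubjectRecord

logger = logging.getLogger(__name__)

N_BINS_DEFAULT = 50
RANGE_LOG10_MS_DEFAULT = (0.5, 5.0)
BANDWIDTH_DEFAULT = 0.1
COVARIATE_NAMES = ["gender_code", "jid_entropy", "log10_median_daily_taps", "screen_size"]


@dataclass(frozen=True)
class JIDGrid:
    """A subject's joint interval distribution on a square grid.

    ``mass[i, j]`` is the probability mass at grid center ``i`` on the
    ITI_k axis and ``j`` on the ITI_{k+1} axis; the whole grid sums to one.
    """

    mass: np.ndarray
    grid_centers: np.ndarray
    bandwidth: float
    n_pairs_used: int


@dataclass(frozen=True)
class FeatureVector:
    """Ordered model input for one subject (2500 JID cells + 4 covariates)."""

    values: np.ndarray
    subject_id: str
    chronological_age: float
    cohort_label: str


def grid_centers(
    n_bins: int = N_BINS_DEFAULT,
    range_log10_ms: tuple[float, float] = RANGE_LOG10_MS_DEFAULT,
) -> np.ndarray:
    """Equally spaced cell centers in log10-ms, endpoints included."""
    return np.linspace(range_log10_ms[0], range_log10_ms[1], n_bins)


def gaussian_kernel_grid(
    log_x: np.ndarray, log_y: np.ndarray, centers: np.ndarray, bandwidth: float
) -> np.ndarray:
    """Unnormalized isotropic Gaussian kernel sums on the grid.

    Exploits separability: the (n_pairs, n_bins) kernel matrices along each
    axis multiply into the full grid, equivalent to the direct double loop
    over pairs and cells.
    """
    dx = (log_x[:, None] - centers[None, :]) / bandwidth
    dy = (log_y[:, None] - centers[None, :]) / bandwidth
    kx = np.exp(-0.5 * dx**2)
    ky = np.exp(-0.5 * dy**2)
    return kx.T @ ky


def compute_jid(
    pairs: ITIPairSet,
    bandwidth: float = BANDWIDTH_DEFAULT,
    n_bins: int = N_BINS_DEFAULT,
    range_log10_ms: tuple[float, float] = RANGE_LOG10_MS_DEFAULT,
) -> JIDGrid:
    """Estimate the joint interval distribution of one subject.

    Pairs falling outside the grid range still contribute kernel mass to
    in-grid cells; mass outside the grid is discarded by the final
    renormalization.

    Raises ``ValueError`` for a non-positive bandwidth, or for an empty
    pair set (such subjects must be excluded upstream).
    """
    if bandwidth <= 0:
        raise ValueError(f"bandwidth must be positive, got {bandwidth}")
    if pairs.pairs.shape[0] == 0:
        raise ValueError(
            f"subject {pairs.subject_id!r} has no ITI pairs; exclude it from the analysis"
        )
    if np.any(pairs.pairs <= 0):
        raise ValueError("all ITIs must be positive")
    centers = grid_centers(n_bins, range_log10_ms)
    log_pairs = np.log10(pairs.pairs.astype(float))
    density = gaussian_kernel_grid(log_pairs[:, 0], log_pairs[:, 1], centers, bandwidth)
    total = density.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError(
            f"subject {pairs.subject_id!r}: no kernel mass falls on the grid"
        )
    return JIDGrid(
        mass=density / total,
        grid_centers=centers,
        bandwidth=bandwidth,
        n_pairs_used=int(pairs.pairs.shape[0]),
    )


def jid_entropy(grid: JIDGrid) -> float:
    """Shannon entropy of the JID in bits, with 0*log2(0) := 0."""
    p = grid.mass
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("JID grid is not normalized; cannot compute entropy")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def feature_names(n_bins: int = N_BINS_DEFAULT) -> list[str]:
    """Ordered names of all 2504 features (JID cells row-major, covariates)."""
    names = [f"jid_{i:02d}_{j:02d}" for i in range(n_bins) for j in range(n_bins)]
    return names + list(COVARIATE_NAMES)


def assemble_features(
    grid: JIDGrid, record: SubjectRecord, taps_per_day: np.ndarray
) -> FeatureVector:
    """Concatenate the JID cells and covariates in the canonical order."""
    if record.screen_size is None or not np.isfinite(record.screen_size):
        raise ValueError(
            f"subject {record.subject_id!r} has no screen_size; covariates are not imputed"
        )
    taps = np.asarray(taps_per_day, dtype=float)
    if taps.size == 0 or np.any(taps <= 0):
        raise ValueError(f"subject {record.subject_id!r}: taps_per_day must be positive")
    values = np.concatenate(
        [
            grid.mass.ravel(order="C"),
            [
                float(record.gender_code),
                jid_entropy(grid),
                float(np.log10(np.median(taps))),
                float(record.screen_size),
            ],
        ]
    )
    return FeatureVector(
        values=values,
        subject_id=record.subject_id,
        chronological_age=record.chronological_age,
        cohort_label=record.cohort_label,
    )


@dataclass
class FeatureTable:
    """Feature matrix for a cohort plus alignment metadata.

    ``window_days`` records the accumulation window the features were built
    with, so that a model trained on one window refuses features from
    another.
    """

    X: np.ndarray
    subject_ids: list[str]
    ages: np.ndarray
    cohort_labels: list[str]
    window_days: int
    feature_names: list[str]

    def __len__(self) -> int:
        return self.X.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, "subject_id", self.subject_ids)
        df.insert(1, "chronological_age", self.ages)
        df.insert(2, "cohort_label", self.cohort_labels)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)
        meta = Path(str(path) + ".meta.json")
        meta.write_text(f'{{"window_days": {self.window_days}}}\n')

    @classmethod
    def from_csv(cls, path: str | Path, window_days: int | None = None) -> "FeatureTable":
        df = pd.read_csv(path)
        if window_days is None:
            meta = Path(str(path) + ".meta.json")
            if not meta.exists():
                raise ValueError(f"window_days not given and no sidecar at {meta}")
            import json

            window_days = int(json.loads(meta.read_text())["window_days"])
        names = [c for c in df.columns if c not in ("subject_id", "chronological_age", "cohort_label")]
        return cls(
            X=df[names].to_numpy(dtype=float),
            subject_ids=[str(s) for s in df["subject_id"]],
            ages=df["chronological_age"].to_numpy(dtype=float),
            cohort_labels=[str(c) for c in df["cohort_label"]],
            window_days=window_days,
            feature_names=names,
        )


def build_feature_table(
    streams,
    records,
    window_days: int,
    bandwidth: float = BANDWIDTH_DEFAULT,
    n_bins: int = N_BINS_DEFAULT,
    range_log10_ms: tuple[float, float] = RANGE_LOG10_MS_DEFAULT,
) -> FeatureTable:
    """Featurize a cohort: accumulate, pair, smooth, and assemble.

    Subjects whose (possibly truncated) stream yields no ITI pairs are
    dropped with a logged count.
    """
    from .io import accumulate_window, extract_iti_pairs

    by_id = {s.subject_id: s for s in streams}
    vectors: list[FeatureVector] = []
    dropped = 0
    for rec in records:
        stream = by_id[rec.subject_id]
        windowed = accumulate_window(stream, window_days)
        pair_set = extract_iti_pairs(windowed)
        if pair_set.pairs.shape[0] == 0:
            dropped += 1
            continue
        grid = compute_jid(pair_set, bandwidth, n_bins, range_log10_ms)
        vectors.append(assemble_features(grid, rec, pair_set.taps_per_day))
    if dropped:
        logger.info("dropped %d subjects without ITI pairs at window %d", dropped, window_days)
    if not vectors:
        raise ValueError("no subject produced any ITI pairs")
    return FeatureTable(
        X=np.stack([v.values for v in vectors]),
        subject_ids=[v.subject_id for v in vectors],
        ages=np.array([v.chronological_age for v in vectors]),
        cohort_labels=[v.cohort_label for v in vectors],
        window_days=window_days,
        feature_names=feature_names(n_bins),
    )
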