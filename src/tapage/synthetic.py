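"""Synthetic tappigraphy cohorts.

Smartphone touchscreen interactions ("tappigraphy") form a bursty point
process: runs of sub-second taps (typing), second-scale taps (browsing),
multi-second pauses (reading), and long gaps between sessions.  This module
simulates per-subject streams of interaction timestamps whose *next-interval*
dynamics carry an age signal: the probability of fast (~100 ms) consecutive
inter-touch intervals declines with age while slower intervals become more
common.

The generative model is a Markov mixture of log-normal inter-touch-interval
(ITI) regimes.  Each subject has mixture weights obtained by a softmax over
regime logits that are linear in age (plus a subject-level random effect);
a persistence probability makes consecutive intervals serially dependent so
that the joint distribution of (ITI_k, ITI_{k+1}) is not an outer product.
Disease cohorts are simulated by shifting the *effective* age used for the
mixture weights by a configurable number of years while the stored
chronological age is untouched ("advanced behavioral age").

All magnitudes (regime locations, logits, slopes, taps per day) are invented
generator plumbing: only the direction of the age effect is anchored in
observed smartphone behavior.  Defaults were fixed once so that a healthy
cohort spanning ages 16-86 yields normative-model performance on the scale
reported for human cohorts (mean absolute error around 6 years) and never
revisited.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: milliseconds per calendar day
DAY_MS = 86_400_000

#: reference age (years) at which the base regime logits apply
AGE_REFERENCE = 50.0


class ConfigurationError(ValueError):
    """Raised when a generator configuration is internally inconsistent."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic tappigraphy generator.

    Attributes
    ----------
    n_subjects:
        Number of subjects to simulate.
    age_range:
        (low, high) chronological ages in years, sampled uniformly.
    days_range:
        (low, high) number of recording days per subject, sampled uniformly.
    regime_centers:
        log10-ms locations of the ITI mixture components
        (fast ~100 ms, medium ~1 s, slow ~4 s, gap ~30 s).
    regime_sd:
        log10-ms spread of each component.
    base_logits:
        Mixture logits at the reference age (50 y).
    age_slopes:
        Change of each regime logit per year of age.  The fast regime slope
        is negative (fast pairs decline with age), slow/gap slopes positive.
    subject_logit_sd:
        Standard deviation of the per-subject random effect added to every
        regime logit (individual variability around the age norm).
    regime_persistence:
        Probability that the next interval stays in the current regime
        (Markov serial dependence); must lie in [0, 1].
    mean_daily_taps:
        Poisson mean of interaction counts per day.
    acceleration_years:
        Additive effective-age offset applied when drawing mixture weights;
        use a positive value for disease cohorts.  The stored chronological
        age is unaffected.
    cohort_label:
        Label written into the subject records ("healthy" or "patient").
    screen_size_range:
        (low, high) screen diagonal in inches, sampled uniformly.
    seed:
        Global seed; per-subject substreams are spawned from it so subject i
        is reproducible independently of cohort size.
    """

    n_subjects: int = 100
    age_range: tuple[float, float] = (16.0, 86.0)
    days_range: tuple[int, int] = (7, 180)
    regime_centers: tuple[float, ...] = (2.0, 3.0, 3.6, 4.5)
    regime_sd: tuple[float, ...] = (0.25, 0.25, 0.25, 0.30)
    base_logits: tuple[float, ...] = (1.2, 0.7, 0.0, -0.9)
    age_slopes: tuple[float, ...] = (-0.030, 0.000, 0.018, 0.016)
    subject_logit_sd: float = 0.30
    regime_persistence: float = 0.5
    mean_daily_taps: float = 250.0
    acceleration_years: float = 0.0
    cohort_label: str = "healthy"
    screen_size_range: tuple[float, float] = (4.5, 6.9)
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 0:
            raise ConfigurationError("n_subjects must be non-negative")
        if self.age_range[0] > self.age_range[1]:
            raise ConfigurationError(f"age_range low > high: {self.age_range}")
        if self.days_range[0] > self.days_range[1]:
            raise ConfigurationError(f"days_range low > high: {self.days_range}")
        if self.days_range[0] < 1:
            raise ConfigurationError("days_range low must be >= 1")
        if not 0.0 <= self.regime_persistence <= 1.0:
            raise ConfigurationError("regime_persistence must lie in [0, 1]")
        n = len(self.regime_centers)
        for name in ("regime_sd", "base_logits", "age_slopes"):
            if len(getattr(self, name)) != n:
                raise ConfigurationError(f"{name} must have {n} entries")
        if self.mean_daily_taps <= 0:
            raise ConfigurationError("mean_daily_taps must be positive")
        if self.subject_logit_sd < 0:
            raise ConfigurationError("subject_logit_sd must be non-negative")


@dataclass(frozen=True)
class TapStream:
    """One subject's ordered touchscreen interaction onsets.

    ``timestamps`` are strictly increasing integer milliseconds from the
    start of the recording.
    """

    subject_id: str
    timestamps: np.ndarray

    @property
    def day_index(self) -> np.ndarray:
        """Integer calendar day of each event."""
        return self.timestamps // DAY_MS

    @property
    def recording_days(self) -> int:
        """Number of distinct calendar days with at least one event."""
        return int(np.unique(self.day_index).size)


@dataclass(frozen=True)
class SubjectRecord:
    """Subject metadata: covariates and cohort label."""

    subject_id: str
    chronological_age: float
    gender_code: int
    screen_size: float
    cohort_label: str
    recording_days: int

    def __post_init__(self):
        if self.gender_code not in (0, 1):
            raise ValueError(f"gender_code must be 0 or 1, got {self.gender_code}")
        if self.chronological_age <= 0:
            raise ValueError("chronological_age must be positive")


def _softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - np.max(z))
    return e / e.sum()


def regime_weights(
    config: GeneratorConfig,
    effective_age: float,
    subject_offsets: np.ndarray | None = None,
) -> np.ndarray:
    """Mixture weights of the ITI regimes at a given effective age.

    Softmax of ``base_logits + age_slopes * (age - 50) [+ subject effect]``;
    always non-negative and summing to one.
    """
    z = np.asarray(config.base_logits, dtype=float) + np.asarray(
        config.age_slopes, dtype=float
    ) * (effective_age - AGE_REFERENCE)
    if subject_offsets is not None:
        z = z + np.asarray(subject_offsets, dtype=float)
    return _softmax(z)


def _simulate_stream(
    rng: np.random.Generator, weights: np.ndarray, n_days: int, config: GeneratorConfig
) -> np.ndarray:
    """Simulate one subject's timestamps (ms, strictly increasing)."""
    counts = rng.poisson(config.mean_daily_taps, n_days)
    counts[counts == 1] = 2  # at least 2 events on any non-empty day
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    day_ids = np.repeat(np.arange(n_days), counts)
    first_of_day = np.ones(total, dtype=bool)
    first_of_day[1:] = day_ids[1:] != day_ids[:-1]

    # Markov regime chain, vectorized: a "fresh" position redraws the regime
    # from the mixture, a "stay" position copies the last fresh draw.
    stay = rng.random(total) < config.regime_persistence
    draws = rng.choice(len(weights), size=total, p=weights)
    fresh = first_of_day | ~stay
    src = np.where(fresh, np.arange(total), -1)
    np.maximum.accumulate(src, out=src)
    regimes = draws[src]

    centers = np.asarray(config.regime_centers)[regimes]
    sds = np.asarray(config.regime_sd)[regimes]
    iti = np.round(10.0 ** rng.normal(centers, sds)).astype(np.int64)
    np.maximum(iti, 1, out=iti)

    # Event times within each day: first event of a day sits at a random
    # morning offset, subsequent events accumulate the drawn intervals.
    cum = np.cumsum(iti)
    base = np.where(first_of_day, cum, 0)
    np.maximum.accumulate(base, out=base)
    rel = cum - base
    offsets = rng.integers(0, DAY_MS // 3, size=n_days)
    within = rel + offsets[day_ids]

    keep = within < DAY_MS  # never spill across midnight
    kept_counts = np.bincount(day_ids[keep], minlength=n_days)
    lonely = kept_counts == 1
    if lonely.any():
        keep &= ~lonely[day_ids]
    return (day_ids[keep] * DAY_MS + within[keep]).astype(np.int64)


def generate_cohort(
    config: GeneratorConfig,
    *,
    ages: Sequence[float] | None = None,
    n_days: Sequence[int] | None = None,
) -> tuple[list[TapStream], list[SubjectRecord]]:
    """Generate tap streams and metadata for one cohort.

    Deterministic given ``config.seed``: each subject draws from its own
    spawned substream, so subject ``i`` is identical regardless of
    ``n_subjects``.  ``ages`` / ``n_days`` optionally pin per-subject values
    (the corresponding random draws are still consumed, so pinned and
    unpinned runs stay aligned on every other draw).

    Disease subjects are simulated at effective age
    ``chronological_age + acceleration_years``; the record stores the
    chronological age.
    """
    config.validate()
    if ages is not None and len(ages) != config.n_subjects:
        raise ConfigurationError("ages override must have n_subjects entries")
    if n_days is not None and len(n_days) != config.n_subjects:
        raise ConfigurationError("n_days override must have n_subjects entries")

    children = np.random.SeedSequence([config.seed]).spawn(config.n_subjects)
    streams: list[TapStream] = []
    records: list[SubjectRecord] = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        age = float(rng.uniform(*config.age_range))
        if ages is not None:
            age = float(ages[i])
        nd = int(rng.integers(config.days_range[0], config.days_range[1] + 1))
        if n_days is not None:
            nd = int(n_days[i])
        gender = int(rng.integers(0, 2))
        screen = round(float(rng.uniform(*config.screen_size_range)), 1)
        offsets = rng.normal(0.0, config.subject_logit_sd, len(config.regime_centers))
        weights = regime_weights(config, age + config.acceleration_years, offsets)

        subject_id = f"{config.cohort_label}_{i:04d}"
        timestamps = _simulate_stream(rng, weights, nd, config)
        stream = TapStream(subject_id=subject_id, timestamps=timestamps)
        streams.append(stream)
        records.append(
            SubjectRecord(
                subject_id=subject_id,
                chronological_age=age,
                gender_code=gender,
                screen_size=screen,
                cohort_label=config.cohort_label,
                recording_days=stream.recording_days,
            )
        )
    return streams, records


METADATA_FILENAME = "cohort.csv"
METADATA_COLUMNS = ["subject_id", "age_years", "gender_code", "screen_size", "cohort_label"]


def write_cohort(
    streams: Sequence[TapStream],
    records: Sequence[SubjectRecord],
    directory: str | Path,
) -> dict:
    """Write one timestamps CSV per subject plus a cohort metadata table.

    Returns a manifest ``{"metadata": path, "subjects": {subject_id: path}}``.
    Round-trips losslessly through :func:`tapage.io.read_cohort`.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        meta_path = directory / METADATA_FILENAME
        with open(meta_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(METADATA_COLUMNS)
            for rec in records:
                writer.writerow(
                    [
                        rec.subject_id,
                        repr(rec.chronological_age),
                        rec.gender_code,
                        rec.screen_size,
                        rec.cohort_label,
                    ]
                )
        manifest: dict = {"metadata": str(meta_path), "subjects": {}}
        for stream in streams:
            path = directory / f"taps_{stream.subject_id}.csv"
            with open(path, "w", newline="") as fh:
                writer = csv.writer(fh)
                writer.writerow(["subject_id", "timestamp_ms"])
                for ts in stream.timestamps:
                    writer.writerow([stream.subject_id, int(ts)])
            manifest["subjects"][stream.subject_id] = str(path)
    except OSError as exc:
        raise OSError(f"failed writing cohort under {directory}: {exc}") from exc
    return manifest


def patient_config(config: GeneratorConfig, acceleration_years: float, seed: int) -> GeneratorConfig:
    """Derive a disease-cohort configuration from a healthy one."""
    return replace(
        config,
        acceleration_years=acceleration_years,
        cohort_label="patient",
        seed=seed,
    )
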