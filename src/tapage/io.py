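"""Reading, filtering and pairing of tappigraphy recordings.

Handles the steps between raw timestamp files and the joint-interval
features: loading a cohort directory, restricting a stream to its first
``max_days`` calendar days (accumulation window), enforcing the minimum
recording-length inclusion filter, and turning timestamps into consecutive
inter-touch-interval (ITI) pairs.

ITI pairs are never formed across a midnight boundary: overnight gaps would
otherwise dominate the slow tail of the joint distribution with artifactual
mass.  Duplicate timestamps (zero intervals) are dropped before pairing
because the features live in log space.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic import DAY_MS, METADATA_FILENAME, SubjectRecord, TapStream

logger = logging.getLogger(__name__)


class CohortReadError(RuntimeError):
    """Raised when a cohort directory is inconsistent (e.g. orphan stream)."""


class EmptyCohortError(RuntimeError):
    """Raised when a filter removes every subject."""


@dataclass(frozen=True)
class ITIPairSet:
    """Consecutive inter-touch-interval pairs for one subject.

    ``pairs`` is an (n, 2) integer array of (ITI_k, ITI_{k+1}) in
    milliseconds; successive rows derived from one unbroken same-day run of
    events overlap in one interval.  ``taps_per_day`` holds interaction
    counts for each day with data.
    """

    subject_id: str
    pairs: np.ndarray
    n_days_used: int
    taps_per_day: np.ndarray


def read_cohort(directory: str | Path) -> tuple[list[TapStream], list[SubjectRecord]]:
    """Read a cohort directory written by :func:`tapage.synthetic.write_cohort`.

    Streams are sorted by timestamp (a warning is logged if sorting was
    needed) and exact duplicate timestamps are dropped with a logged count.
    A stream file without a metadata row is a hard error; a metadata row
    without a stream file is dropped with a warning.
    """
    directory = Path(directory)
    meta_path = directory / METADATA_FILENAME
    if not meta_path.exists():
        raise CohortReadError(f"no cohort metadata table at {meta_path}")
    meta = pd.read_csv(meta_path)

    records_by_id: dict[str, SubjectRecord] = {}
    for row in meta.itertuples(index=False):
        records_by_id[str(row.subject_id)] = SubjectRecord(
            subject_id=str(row.subject_id),
            chronological_age=float(row.age_years),
            gender_code=int(row.gender_code),
            screen_size=float(row.screen_size),
            cohort_label=str(row.cohort_label),
            recording_days=0,  # recomputed from the stream below
        )

    streams: list[TapStream] = []
    records: list[SubjectRecord] = []
    seen: set[str] = set()
    for path in sorted(directory.glob("taps_*.csv")):
        df = pd.read_csv(path)
        if len(df) == 0:
            subject_id = path.stem[len("taps_"):]
        else:
            subject_id = str(df["subject_id"].iloc[0])
        if subject_id not in records_by_id:
            raise CohortReadError(
                f"stream file {path.name} has no metadata row for subject {subject_id!r}"
            )
        ts = df["timestamp_ms"].to_numpy(dtype=np.int64)
        if ts.size and np.any(np.diff(ts) < 0):
            logger.warning("non-monotone timestamps for %s: sorting", subject_id)
            ts = np.sort(ts)
        deduped = np.unique(ts)
        if deduped.size != ts.size:
            logger.warning(
                "dropped %d duplicate timestamps for %s", ts.size - deduped.size, subject_id
            )
        stream = TapStream(subject_id=subject_id, timestamps=deduped)
        streams.append(stream)
        rec = records_by_id[subject_id]
        records.append(
            SubjectRecord(
                subject_id=rec.subject_id,
                chronological_age=rec.chronological_age,
                gender_code=rec.gender_code,
                screen_size=rec.screen_size,
                cohort_label=rec.cohort_label,
                recording_days=stream.recording_days,
            )
        )
        seen.add(subject_id)

    orphans = set(records_by_id) - seen
    if orphans:
        logger.warning("metadata rows without stream files dropped: %s", sorted(orphans))
    return streams, records


def accumulate_window(stream: TapStream, max_days: int) -> TapStream:
    """Restrict a stream to its first ``max_days`` distinct calendar days."""
    if max_days < 1:
        raise ValueError("max_days must be >= 1")
    if stream.timestamps.size == 0:
        return stream
    days = stream.day_index
    distinct = np.unique(days)
    if distinct.size <= max_days:
        return stream
    last = distinct[max_days - 1]
    return TapStream(subject_id=stream.subject_id, timestamps=stream.timestamps[days <= last])


def apply_inclusion_filter(
    records: Sequence[SubjectRecord],
    streams: Sequence[TapStream],
    min_days: int = 7,
) -> tuple[list[TapStream], list[SubjectRecord]]:
    """Keep subjects with at least ``min_days`` distinct days of data.

    The threshold is inclusive: a subject with exactly ``min_days`` recorded
    days is retained.  Raises :class:`EmptyCohortError` if nothing survives.
    """
    by_id = {s.subject_id: s for s in streams}
    kept_streams: list[TapStream] = []
    kept_records: list[SubjectRecord] = []
    removed = 0
    for rec in records:
        stream = by_id.get(rec.subject_id)
        if stream is None or stream.recording_days < min_days:
            removed += 1
            continue
        kept_streams.append(stream)
        kept_records.append(rec)
    if removed:
        logger.info("inclusion filter removed %d of %d subjects", removed, len(records))
    if not kept_records:
        raise EmptyCohortError(f"no subject has >= {min_days} days of recordings")
    return kept_streams, kept_records


def extract_iti_pairs(stream: TapStream) -> ITIPairSet:
    """Compute consecutive ITI pairs, never bridging a day boundary.

    An unbroken run of m same-day events yields m-1 intervals and m-2
    pairs.  Streams with fewer than 3 events yield an empty pair set with a
    logged warning.
    """
    ts = np.unique(stream.timestamps)  # sorted; duplicates (zero ITIs) dropped
    if ts.size != stream.timestamps.size:
        logger.warning(
            "dropped %d duplicate timestamps for %s before pairing",
            stream.timestamps.size - ts.size,
            stream.subject_id,
        )
    days = ts // DAY_MS
    if ts.size:
        unique_days, counts = np.unique(days, return_counts=True)
    else:
        unique_days, counts = np.empty(0, np.int64), np.empty(0, np.int64)

    if ts.size < 3:
        logger.warning("subject %s has <3 events; no ITI pairs", stream.subject_id)
        return ITIPairSet(stream.subject_id, np.empty((0, 2), np.int64), unique_days.size, counts)

    iti = np.diff(ts)
    same_day = days[1:] == days[:-1]
    pair_mask = same_day[:-1] & same_day[1:]
    pairs = np.stack([iti[:-1][pair_mask], iti[1:][pair_mask]], axis=1)
    return ITIPairSet(stream.subject_id, pairs, unique_days.size, counts)


def write_filter_report(path: str | Path, report: dict) -> None:
    """Persist filter decisions (removed subjects, dedup counts) as JSON."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
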