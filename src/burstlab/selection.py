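"""Editor activity normalization, ranking, and super-editor selection.

Normalized activity is an editor's total edit count divided by the number of
days from their first observed edit to the last day of the corpus (not their
own last edit). Super-editors are the unusually active accounts the
conditional-distribution analysis focuses on, because only they provide
enough inter-event samples per one-hour window: among editors with more than
``min_edits`` edits, those whose normalized activity exceeds the eligible-set
mean by more than 25% and who have been active for more than one year.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import ConsistencyError, InsufficientDataError
from .ingest import EventStream

logger = logging.getLogger(__name__)

SECONDS_PER_DAY = 86_400.0


@dataclass(frozen=True)
class EditorActivity:
    user_id: str
    n_edits: int
    first_time: int
    dataset_end: int
    span_days: float
    normalized_activity: float
    rank: int | None = None
    is_super: bool = False


def compute_activity(stream: EventStream, dataset_end: int | None = None) -> EditorActivity:
    """Edits per day over the span from first edit to the corpus last day."""
    if len(stream) == 0:
        raise InsufficientDataError(f"stream {stream.user_id!r} is empty")
    if dataset_end is None:
        dataset_end = stream.dataset_end
    if dataset_end is None:
        raise ConsistencyError("dataset_end required (not attached to stream)")
    first = int(stream.times[0])
    if first > dataset_end:
        raise ConsistencyError(
            f"{stream.user_id!r}: first edit after dataset end"
        )
    span_days = (dataset_end - first) / SECONDS_PER_DAY
    if span_days == 0:
        raise ConsistencyError(f"{stream.user_id!r}: zero activity span")
    return EditorActivity(
        user_id=stream.user_id,
        n_edits=len(stream),
        first_time=first,
        dataset_end=int(dataset_end),
        span_days=span_days,
        normalized_activity=len(stream) / span_days,
    )


def rank_editors(activities: list[EditorActivity]) -> list[EditorActivity]:
    """Rank 1 = highest normalized activity; ties broken by ascending user_id."""
    ordered = sorted(activities, key=lambda a: (-a.normalized_activity, a.user_id))
    return [replace(a, rank=i + 1) for i, a in enumerate(ordered)]


def select_super_editors(
    activities: list[EditorActivity],
    min_edits: int = 2000,
    activity_factor: float = 1.25,
    min_span_days: float = 365.0,
    reference: str = "eligible",
) -> list[EditorActivity]:
    """Apply the eligibility and super-editor filters.

    Eligibility is ``n_edits > min_edits`` (strict). The reference mean is
    the mean normalized activity over the eligible set (``reference=
    "eligible"``, default) or over all editors (``reference="all"``).
    Selected editors satisfy ``activity > activity_factor × mean`` and
    ``span_days > min_span_days``, both strict.
    """
    eligible = [a for a in activities if a.n_edits > min_edits]
    if not eligible:
        logger.warning("select_super_editors: no editors exceed %d edits", min_edits)
        return []
    if reference == "eligible":
        pool = eligible
    elif reference == "all":
        pool = activities
    else:
        raise ValueError(f"unknown reference set {reference!r}")
    mean_activity = float(np.mean([a.normalized_activity for a in pool]))
    threshold = activity_factor * mean_activity
    selected = [
        replace(a, is_super=True)
        for a in sorted(eligible, key=lambda a: a.user_id)
        if a.normalized_activity > threshold and a.span_days > min_span_days
    ]
    logger.info(
        "select_super_editors: %d eligible, mean activity %.4g/day, %d selected",
        len(eligible), mean_activity, len(selected),
    )
    return selected


def activity_table(activities: list[EditorActivity]) -> pd.DataFrame:
    """Rank table (the content behind an activity-vs-rank plot)."""
    ranked = rank_editors(activities)
    return pd.DataFrame(
        [
            {
                "user_id": a.user_id,
                "n_edits": a.n_edits,
                "span_days": round(a.span_days, 6),
                "normalized_activity": round(a.normalized_activity, 6),
                "rank": a.rank,
                "is_super": a.is_super,
            }
            for a in ranked
        ]
    )
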