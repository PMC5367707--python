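"""Hour-of-day-conditioned inter-event samples, PDFs and CCDFs.

The object of study is the conditional density P(τ | n ≤ t < n+1): the
distribution of the waiting time τ (minutes) to the next event, given that
the event opening the gap occurred in hour-of-day window [n, n+1), n = 0..23
(UTC calendar hour of the epoch timestamp). A gap is always attributed to
the hour of its *initiating* event. Gaps longer than 1440 min (one day) are
discarded so a window cannot overlap the same hour of the following day.
Windows with too few gaps are masked out rather than deleted, so retention
is reversible and auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, InvalidParameterError
from .ingest import EventStream

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF_MIN = 1440.0
DEFAULT_MIN_COUNT = 50


@dataclass(frozen=True)
class InterEventSample:
    """Inter-event durations in minutes, all > 0, with a conditioning label."""

    values: np.ndarray
    label: str = "all"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.size and values.min() <= 0:
            raise InvalidParameterError("inter-event times must be positive")

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class WindowedInterEvents:
    """Per-hour conditional samples with a retained-window mask."""

    samples: tuple[InterEventSample, ...]  # 24 entries, hour n at index n
    retained_mask: np.ndarray  # 24 booleans
    min_count: int | None = None

    def __post_init__(self) -> None:
        if len(self.samples) != 24:
            raise InvalidParameterError("need exactly 24 hour windows")
        mask = np.asarray(self.retained_mask, dtype=bool)
        object.__setattr__(self, "retained_mask", mask)
        if mask.shape != (24,):
            raise InvalidParameterError("retained_mask must have 24 entries")

    @property
    def counts(self) -> np.ndarray:
        return np.array([len(s) for s in self.samples])

    @property
    def retained_hours(self) -> list[int]:
        return [h for h in range(24) if self.retained_mask[h]]


def inter_event_times(stream: EventStream) -> InterEventSample:
    """All successive gaps of one stream, in minutes."""
    if len(stream) < 2:
        raise InsufficientDataError(
            f"{stream.user_id!r}: need at least 2 events for inter-event times"
        )
    gaps = np.diff(stream.times) / 60.0
    return InterEventSample(values=gaps, label="all")


def condition_on_hour(stream: EventStream) -> WindowedInterEvents:
    """Partition gaps by the UTC hour of day of each gap's initiating event."""
    if len(stream) < 2:
        raise InsufficientDataError(
            f"{stream.user_id!r}: need at least 2 events for inter-event times"
        )
    gaps = np.diff(stream.times) / 60.0
    hours = (stream.times[:-1] % 86_400) // 3600
    samples = tuple(
        InterEventSample(values=gaps[hours == h], label=f"hour-{h:02d}")
        for h in range(24)
    )
    mask = np.array([len(s) > 0 for s in samples])
    return WindowedInterEvents(samples=samples, retained_mask=mask)


def apply_cutoff(sample: InterEventSample, max_minutes: float = DEFAULT_CUTOFF_MIN) -> InterEventSample:
    """Drop gaps above the cutoff (inclusive boundary: τ == cutoff is kept)."""
    kept = sample.values[sample.values <= max_minutes]
    removed = len(sample) - kept.size
    if removed:
        logger.info("cutoff %.0f min: removed %d of %d gaps (%s)",
                    max_minutes, removed, len(sample), sample.label)
    return InterEventSample(values=kept, label=sample.label)


def cutoff_windows(
    windowed: WindowedInterEvents, max_minutes: float = DEFAULT_CUTOFF_MIN
) -> WindowedInterEvents:
    """Apply the cutoff inside every hour window (masks are recomputed later)."""
    samples = tuple(apply_cutoff(s, max_minutes) for s in windowed.samples)
    mask = np.array([len(s) > 0 for s in samples])
    return WindowedInterEvents(samples=samples, retained_mask=mask,
                               min_count=windowed.min_count)


def retain_windows(windowed: WindowedInterEvents, min_count: int) -> WindowedInterEvents:
    """Mask windows with fewer than ``min_count`` gaps; data are preserved."""
    if min_count < 1:
        raise InvalidParameterError("min_count must be at least 1")
    mask = windowed.counts >= min_count
    logger.info("retain_windows: %d of 24 windows retained at min_count=%d",
                int(mask.sum()), min_count)
    return WindowedInterEvents(samples=windowed.samples, retained_mask=mask,
                               min_count=min_count)


def pooled(windowed: WindowedInterEvents, retained_only: bool = False) -> InterEventSample:
    """Concatenate hour windows back into one sample (the 24-hour window)."""
    parts = [
        s.values for h, s in enumerate(windowed.samples)
        if not retained_only or windowed.retained_mask[h]
    ]
    values = np.concatenate(parts) if parts else np.empty(0)
    return InterEventSample(values=values, label="all")


@dataclass(frozen=True)
class PDFEstimate:
    """Log-binned density estimate: ``densities[i]`` over ``[edges[i], edges[i+1])``."""

    edges: np.ndarray
    densities: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return np.sqrt(self.edges[:-1] * self.edges[1:])

    @property
    def integral(self) -> float:
        return float(np.sum(self.densities * np.diff(self.edges)))


@dataclass(frozen=True)
class CCDFEstimate:
    """Empirical tail function: ``tail_prob[i] = P(X > support[i])``."""

    support: np.ndarray
    tail_prob: np.ndarray

    def __call__(self, x: float) -> float:
        idx = np.searchsorted(self.support, x, side="right")
        return 1.0 if idx == 0 else float(self.tail_prob[idx - 1])


def log_binned_pdf(sample: InterEventSample, bins_per_decade: int = 10) -> PDFEstimate:
    """Histogram density on logarithmically spaced bins (display only;
    all fitting uses the raw values)."""
    if len(sample) == 0:
        raise InsufficientDataError("cannot estimate a PDF from an empty sample")
    v = sample.values
    lo, hi = np.log10(v.min()), np.log10(v.max())
    if lo == hi:  # all values equal: one tight bin holding all mass
        edges = np.array([v.min() * 0.999, v.max() * 1.001])
    else:
        n_bins = max(1, int(np.ceil((hi - lo) * bins_per_decade)))
        edges = np.logspace(lo, hi, n_bins + 1)
        edges[-1] = np.nextafter(edges[-1], np.inf)  # keep the max inside
    counts, edges = np.histogram(v, bins=edges)
    densities = counts / (v.size * np.diff(edges))
    return PDFEstimate(edges=edges, densities=densities)


def empirical_ccdf(sample: InterEventSample) -> CCDFEstimate:
    """Fraction of values strictly greater than x, at each distinct value."""
    if len(sample) == 0:
        raise InsufficientDataError("cannot estimate a CCDF from an empty sample")
    support, counts = np.unique(sample.values, return_counts=True)
    n = sample.values.size
    tail = 1.0 - np.cumsum(counts) / n
    return CCDFEstimate(support=support, tail_prob=tail)


def window_count_table(windowed: WindowedInterEvents) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "hour": np.arange(24),
            "n_gaps": windowed.counts,
            "retained": windowed.retained_mask,
        }
    )
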