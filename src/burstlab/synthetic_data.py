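"""Synthetic circadian-cascade event streams with known ground truth.

The generative picture: a user's day has a 24-hour rhythm that modulates how
often they *start* an activity session, but once a session has started the
follow-up actions arrive with heavy-tailed (Pareto) waiting times that do not
depend on the clock. Concretely,

* from the end of the previous session, the next initiation arrives from an
  inhomogeneous Poisson process whose rate is piecewise-constant over
  hour-of-day (a :class:`CircadianProfile`, repeated over ``span_days``);
  sessions never overlap, since one person acts sequentially;
* each initiation triggers ``K`` follow-up events, ``K`` geometric on
  ``{0, 1, 2, ...}`` with continuation probability ``cascade_continue_prob``;
* successive intra-cascade gaps are iid Pareto with PDF exponent magnitude
  ``pareto_shape`` (density ``p(τ) ∝ τ^{-a}`` above ``xmin_minutes``), upper
  truncated at 1440 min so that planted exponents remain identifiable after
  the one-day analysis cutoff.

In *stationary* mode (all ``hour_shape_offsets`` zero) the conditional
inter-event distribution is the same in every hour window; the *control*
mode plants an hour-dependent exponent via per-hour shape offsets, giving a
negative control for stationarity tests. Populations additionally plant
super-editors (higher initiation rate) and bots (flagged in truth metadata
and given ``...Bot`` ids so the ingest filter catches them).

Everything is reproducible: a root seed spawns per-user integer seeds via a
counter scheme, and every sampler takes an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .ingest import SOURCE_SYNTHETIC, EventStream, write_timestamp_list

SECONDS_PER_DAY = 86_400
CASCADE_GAP_CAP_MIN = 1440.0  # mirrors the one-day analysis cutoff


@dataclass(frozen=True)
class CircadianProfile:
    """Cascade-initiation rates per hour of day (initiations/hour), length 24."""

    hourly_rate: np.ndarray

    def __post_init__(self) -> None:
        rate = np.asarray(self.hourly_rate, dtype=float)
        object.__setattr__(self, "hourly_rate", rate)
        if rate.shape != (24,):
            raise InvalidParameterError("hourly_rate must have exactly 24 entries")
        if np.any(rate < 0):
            raise InvalidParameterError("hourly rates must be non-negative")

    @classmethod
    def flat(cls, rate: float) -> "CircadianProfile":
        return cls(np.full(24, float(rate)))

    @classmethod
    def diurnal(cls, scale: float = 1.0) -> "CircadianProfile":
        """A stylized human day: night rest (02–06h), daytime work, evening peak."""
        rate = np.array(
            [0.05, 0.02, 0.0, 0.0, 0.0, 0.0, 0.0, 0.05,
             0.10, 0.20, 0.20, 0.20, 0.15, 0.20, 0.20, 0.20,
             0.20, 0.20, 0.25, 0.30, 0.30, 0.25, 0.15, 0.08]
        )
        return cls(rate * scale)

    @property
    def daily_total(self) -> float:
        return float(self.hourly_rate.sum())


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the circadian-cascade generator.

    ``pareto_shape`` is the magnitude ``a`` of the PDF exponent (planted
    ``α = −a``); it must exceed 1 for a normalizable density.
    """

    n_users: int = 12
    span_days: int = 400
    pareto_shape: float = 2.0
    xmin_minutes: float = 1.0
    cascade_continue_prob: float = 0.6
    hour_shape_offsets: np.ndarray = field(default_factory=lambda: np.zeros(24))
    bot_fraction: float = 0.0
    super_fraction: float = 0.0
    super_rate_factor: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        offsets = np.asarray(self.hour_shape_offsets, dtype=float)
        object.__setattr__(self, "hour_shape_offsets", offsets)
        if offsets.shape != (24,):
            raise InvalidParameterError("hour_shape_offsets must have exactly 24 entries")
        if self.pareto_shape <= 1:
            raise InvalidParameterError("pareto_shape must exceed 1")
        if np.any(self.pareto_shape + offsets <= 1):
            raise InvalidParameterError("effective per-hour shape must exceed 1")
        if self.xmin_minutes <= 0:
            raise InvalidParameterError("xmin_minutes must be positive")
        if not 0 <= self.cascade_continue_prob < 1:
            raise InvalidParameterError("cascade_continue_prob must lie in [0, 1)")
        if not 0 <= self.bot_fraction <= 1:
            raise InvalidParameterError("bot_fraction must lie in [0, 1]")
        if self.span_days <= 0:
            raise InvalidParameterError("span_days must be positive")

    @property
    def dataset_end(self) -> int:
        return self.span_days * SECONDS_PER_DAY

    @property
    def stationary(self) -> bool:
        return bool(np.all(self.hour_shape_offsets == 0))


@dataclass
class SimulatedPopulation:
    """Generated streams plus the planted truth used as test oracle."""

    streams: list[EventStream]
    truth: pd.DataFrame  # user_id, shape, is_bot, is_super, rate_factor
    config: GeneratorConfig


def sample_pareto(shape: float, xmin: float, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` iid Pareto variates with density ``p(x) ∝ x^{-shape}``, x ≥ xmin.

    Inverse-transform sampling: survival ``S(x) = (x/xmin)^{1-shape}``.
    """
    if shape <= 1:
        raise InvalidParameterError("shape must exceed 1")
    if xmin <= 0:
        raise InvalidParameterError("xmin must be positive")
    if n < 0:
        raise InvalidParameterError("n must be non-negative")
    rng = np.random.default_rng(seed)
    return _pareto(rng, shape, xmin, n)


def _pareto(rng: np.random.Generator, shape: float, xmin: float, n: int) -> np.ndarray:
    u = rng.random(n)
    return xmin * (1.0 - u) ** (-1.0 / (shape - 1.0))


def _truncated_pareto(
    rng: np.random.Generator, shape: np.ndarray | float, xmin: float, xmax: float, n: int
) -> np.ndarray:
    """Exact inverse-CDF draw from a Pareto upper-truncated at ``xmax``."""
    b = np.asarray(shape, dtype=float) - 1.0
    s = (xmax / xmin) ** (-b)  # survival mass beyond the cap
    u = rng.random(n)
    return xmin * (1.0 - u * (1.0 - s)) ** (-1.0 / b)


def _strictify(times: np.ndarray) -> np.ndarray:
    """Resolve ties by minimal +1 s shifts, preserving order and count."""
    if times.size == 0:
        return times
    idx = np.arange(times.size, dtype=np.int64)
    return np.maximum.accumulate(times - idx) + idx


def _next_initiation(
    rng: np.random.Generator, t: float, hourly_rate: np.ndarray, end: float
) -> float | None:
    """First point after ``t`` of an inhomogeneous Poisson process with
    piecewise-constant hour-of-day rates (events/hour), or None past ``end``.

    Standard time-change construction: draw E ~ Exp(1) and walk hour slots
    until the integrated rate reaches E.
    """
    target = rng.exponential()
    slot = int(t // 3600)
    frac = (t - slot * 3600) / 3600.0  # fraction of the current slot already spent
    while slot * 3600 < end:
        rate = hourly_rate[slot % 24]
        budget = rate * (1.0 - frac)
        if rate > 0 and budget >= target:
            return (slot + frac + target / rate) * 3600.0
        target -= budget
        slot += 1
        frac = 0.0
    return None


def generate_user_stream(
    profile: CircadianProfile,
    config: GeneratorConfig,
    user_seed: int,
    user_id: str = "synthetic-user",
    rate_factor: float = 1.0,
) -> EventStream:
    """Simulate one user's stream over ``config.span_days`` days.

    The user is an alternating renewal process: from the end of the previous
    cascade, the next initiation arrives from an inhomogeneous Poisson
    process with the hourly profile (times ``rate_factor``) repeated daily;
    the initiation triggers a cascade of K further events (K geometric),
    with truncated-Pareto gaps whose shape is ``pareto_shape +
    hour_shape_offsets[h]``, h the hour of day of the event opening each
    gap. Cascades never overlap — one person edits sequentially — so the
    merged stream's intra-cascade gaps follow the planted law exactly.
    Timestamps are floored to 1 s resolution, tie-shifted to be strictly
    increasing, and clipped to the simulated span.
    """
    rng = np.random.default_rng(user_seed)
    end = float(config.dataset_end)
    rates = profile.hourly_rate * rate_factor
    if rates.sum() == 0:
        return EventStream(
            user_id=user_id, times=np.empty(0, dtype=np.int64),
            source=SOURCE_SYNTHETIC, dataset_end=config.dataset_end,
        )
    q = 1.0 - config.cascade_continue_prob
    stationary = config.stationary
    base = config.pareto_shape
    offsets = config.hour_shape_offsets

    events: list[float] = []
    chunks: list[np.ndarray] = []
    t = 0.0
    while True:
        nxt = _next_initiation(rng, t, rates, end)
        if nxt is None:
            break
        t = nxt
        events.append(t)
        k = int(rng.geometric(q)) - 1
        if k == 0:
            continue
        if stationary:
            gaps = _truncated_pareto(rng, base, config.xmin_minutes,
                                     CASCADE_GAP_CAP_MIN, k)
            cascade = t + 60.0 * np.cumsum(gaps)
            chunks.append(cascade)
            t = float(cascade[-1])
        else:
            for _ in range(k):
                h = int(t // 3600) % 24
                gap = _truncated_pareto(rng, base + offsets[h],
                                        config.xmin_minutes, CASCADE_GAP_CAP_MIN, 1)
                t += 60.0 * float(gap[0])
                events.append(t)

    parts = [np.asarray(events)] + chunks
    times = np.sort(np.concatenate(parts)).astype(np.int64)
    times = _strictify(times)
    times = times[(times >= 0) & (times < config.dataset_end)]
    return EventStream(
        user_id=user_id, times=times, source=SOURCE_SYNTHETIC,
        dataset_end=config.dataset_end,
    )


def _user_seed(root_seed: int, index: int) -> int:
    # counter scheme: reproducible, independent across users, < 2**31
    return int((root_seed * 1_000_003 + 7919 * index + 1) % 2_147_483_647)


def generate_population(
    config: GeneratorConfig, profile: CircadianProfile | None = None
) -> SimulatedPopulation:
    """Generate ``n_users`` streams with planted bots and super-editors.

    Roles are assigned deterministically: the first ``round(super_fraction ·
    n_users)`` users are super-editors (initiation rate multiplied by
    ``super_rate_factor``), the last ``round(bot_fraction · n_users)`` are
    bots (flagged in truth, ids suffixed ``Bot``). With the default factor
    the planted supers exceed 1.25× the population-mean normalized activity
    by construction.
    """
    if profile is None:
        profile = CircadianProfile.diurnal()
    n = config.n_users
    n_bots = int(round(config.bot_fraction * n))
    n_super = int(round(config.super_fraction * n))
    if n_super + n_bots > n:
        raise InvalidParameterError("bot and super fractions overlap")

    streams: list[EventStream] = []
    rows = []
    for i in range(n):
        is_super = i < n_super
        is_bot = i >= n - n_bots
        uid = f"user{i:04d}Bot" if is_bot else f"user{i:04d}"
        factor = config.super_rate_factor if is_super else 1.0
        stream = generate_user_stream(
            profile, config, _user_seed(config.seed, i), user_id=uid, rate_factor=factor
        )
        streams.append(stream)
        rows.append(
            {
                "user_id": uid,
                "shape": config.pareto_shape,
                "is_bot": is_bot,
                "is_super": is_super,
                "rate_factor": factor,
                "n_events": len(stream),
            }
        )
    truth = pd.DataFrame(rows, columns=["user_id", "shape", "is_bot", "is_super", "rate_factor", "n_events"])
    return SimulatedPopulation(streams=streams, truth=truth, config=config)


def inject_hour_heterogeneity(config: GeneratorConfig, amplitude: float) -> GeneratorConfig:
    """Plant a sinusoidal hour-of-day modulation of the Pareto shape.

    ``shape(h) = pareto_shape + amplitude · sin(2πh/24)``. The negative
    control for stationarity: downstream per-hour fits should recover this
    sinusoid. ``amplitude = 0`` preserves stationary mode.
    """
    if amplitude < 0:
        raise InvalidParameterError("amplitude must be non-negative")
    offsets = amplitude * np.sin(2.0 * np.pi * np.arange(24) / 24.0)
    if np.any(config.pareto_shape + offsets <= 1):
        raise InvalidParameterError(
            "amplitude drives the effective shape to 1 or below in some hour"
        )
    return replace(config, hour_shape_offsets=offsets)


def write_population(population: SimulatedPopulation, outdir: str | Path) -> Path:
    """Write streams as timestamp lists plus a delimited truth table.

    Returns the output directory. Formats match what :mod:`burstlab.ingest`
    reads back, so synthetic runs exercise the real I/O path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for stream in population.streams:
        write_timestamp_list(stream, outdir / f"{stream.user_id}.txt")
    population.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return outdir
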