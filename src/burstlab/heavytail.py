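"""Pareto tail fitting, goodness of fit, and exponent-stationarity statistics.

Model: the conditional inter-event density above a lower bound ``xmin`` is a
power law ``P(τ) = c τ^α`` with PDF exponent ``α < −1``; we write ``a = −α``
for its magnitude (the *shape*). The continuous maximum-likelihood estimator
at known ``xmin`` is the closed form

    â = 1 + n · [Σ ln(τ_i / xmin)]⁻¹ ,

and ``xmin`` itself is chosen by minimizing the Kolmogorov–Smirnov distance
between the fitted tail CDF and the empirical tail CDF over a grid of
candidate values. Because the analysis imposes a one-day cutoff, an
upper-truncated variant (``xmax``) is provided: its likelihood equation is
solved numerically and removes the upward bias the cutoff induces on heavy
tails. Goodness of fit uses a semiparametric bootstrap: synthetic samples
mix draws from the fitted tail model with resamples of the sub-``xmin``
data, and the p-value is the fraction of synthetic KS (or Anderson–Darling)
statistics at least as large as the observed one.

Stationarity across the day is summarized per editor by the per-window
exponents α_i, their mean ⟨α⟩ = Σ_i α_i / N, and the relative deviations
(α_i − ⟨α⟩)/⟨α⟩; per corpus by pooling relative deviations across editors
and moment-matching a normal distribution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .errors import DegenerateSampleError, InsufficientDataError, InvalidParameterError
from .interevent import InterEventSample, WindowedInterEvents

logger = logging.getLogger(__name__)

DEFAULT_MIN_TAIL_SIZE = 50
DEFAULT_MAX_XMIN_CANDIDATES = 250


@dataclass(frozen=True)
class PowerLawFit:
    """A fitted Pareto tail. ``alpha`` is the (negative) PDF exponent."""

    alpha: float
    xmin: float
    n_tail: int
    ks_stat: float
    xmax: float | None = None

    @property
    def shape(self) -> float:
        """Magnitude a = −α of the PDF exponent."""
        return -self.alpha

    @property
    def c(self) -> float:
        """Normalization constant of p(τ) = c τ^α on [xmin, xmax or ∞)."""
        b = self.shape - 1.0
        if self.xmax is None:
            return b * self.xmin ** b
        s = (self.xmax / self.xmin) ** (-b)
        return b * self.xmin ** b / (1.0 - s)

    @property
    def se_shape(self) -> float:
        """Asymptotic standard error of the shape estimate."""
        return (self.shape - 1.0) / np.sqrt(self.n_tail)

    def cdf(self, x: np.ndarray) -> np.ndarray:
        b = self.shape - 1.0
        base = 1.0 - (np.asarray(x, dtype=float) / self.xmin) ** (-b)
        if self.xmax is None:
            return base
        s = (self.xmax / self.xmin) ** (-b)
        return base / (1.0 - s)


@dataclass(frozen=True)
class GOFResult:
    test: str
    statistic: float
    p_value: float
    accepted_at_5pct: bool
    n_boot: int
    seed: int


@dataclass(frozen=True)
class FitPolicy:
    """How per-window exponents are obtained.

    ``fixed_xmin=None`` selects xmin per window by KS minimization; a number
    fixes it for every window. ``xmax`` should equal the analysis cutoff when
    fitting cutoff-truncated data (removes truncation bias), or ``None`` for
    the plain unbounded-tail fit.
    """

    fixed_xmin: float | None = None
    xmax: float | None = None
    min_tail_size: int = DEFAULT_MIN_TAIL_SIZE
    max_candidates: int = DEFAULT_MAX_XMIN_CANDIDATES


@dataclass
class ExponentSummary:
    """Per-editor exponent stationarity summary across retained hour windows."""

    editor_id: str
    hours: list[int]
    window_alphas: np.ndarray
    window_ses: np.ndarray
    skipped_hours: list[int] = field(default_factory=list)
    fits: dict[int, PowerLawFit] = field(default_factory=dict)

    @property
    def n_windows(self) -> int:
        return len(self.hours)

    @property
    def mean_alpha(self) -> float:
        return float(np.mean(self.window_alphas))

    @property
    def rel_devs(self) -> np.ndarray:
        m = self.mean_alpha
        return (self.window_alphas - m) / m

    @property
    def se_mean_alpha(self) -> float:
        return float(np.sqrt(np.sum(self.window_ses**2)) / self.n_windows)


@dataclass
class PopulationSummary:
    """Across-editor pooling of mean exponents and relative deviations."""

    mean_alphas: np.ndarray
    pooled_rel_devs: np.ndarray
    normal_fit: tuple[float, float]  # (mean, sd) by moment matching

    @property
    def mean_of_means(self) -> float:
        return float(np.mean(self.mean_alphas))


def _values(sample: InterEventSample | np.ndarray) -> np.ndarray:
    if isinstance(sample, InterEventSample):
        return sample.values
    return np.asarray(sample, dtype=float)


def _ks_tail(sorted_tail: np.ndarray, fit: PowerLawFit) -> float:
    """sup |fitted CDF − empirical CDF| over the tail sample."""
    n = sorted_tail.size
    model = fit.cdf(sorted_tail)
    grid = np.arange(n + 1) / n
    return float(np.max(np.maximum(model - grid[:-1], grid[1:] - model)))


def _ad_tail(sorted_tail: np.ndarray, fit: PowerLawFit) -> float:
    """Anderson–Darling A² of the tail sample against the fitted Pareto."""
    n = sorted_tail.size
    z = np.clip(fit.cdf(sorted_tail), 1e-12, 1.0 - 1e-12)
    k = np.arange(1, n + 1)
    return float(-n - np.mean((2 * k - 1) * (np.log(z) + np.log(1.0 - z[::-1]))))


def _solve_truncated_shape(mean_log: float, log_ratio: float) -> float:
    """Solve the truncated-Pareto likelihood equation for b = a − 1.

    ``mean_log`` is the tail average of ln(x/xmin); ``log_ratio`` is
    ln(xmax/xmin). The score equation is mean_log = 1/b − s·lnR/(1−s) with
    s = e^{−b·lnR}; the right-hand side decreases from lnR/2 (b→0) to 0.
    """
    if mean_log >= log_ratio / 2.0 - 1e-12:
        raise DegenerateSampleError(
            "tail is at least as heavy as log-uniform; truncated shape at boundary"
        )

    def score(b: float) -> float:
        # s·lnR/(1−s) = lnR/expm1(b·lnR), stable for small b
        t = min(b * log_ratio, 700.0)  # expm1 saturates; the term vanishes anyway
        return 1.0 / b - log_ratio / np.expm1(t) - mean_log

    return float(optimize.brentq(score, 1e-8, 1e6, xtol=1e-12, rtol=1e-14))


def mle_shape(
    sample: InterEventSample | np.ndarray,
    xmin: float,
    xmax: float | None = None,
    min_tail_size: int = DEFAULT_MIN_TAIL_SIZE,
) -> PowerLawFit:
    """Continuous Pareto MLE at fixed ``xmin`` (optionally upper-truncated).

    With ``xmax=None`` this is the closed-form estimator
    ``â = 1 + n/Σ ln(τ/xmin)``; with an ``xmax`` (e.g. the 1440-min analysis
    cutoff) the truncated likelihood equation is solved numerically.
    """
    if xmin <= 0:
        raise InvalidParameterError("xmin must be positive")
    if xmax is not None and xmax <= xmin:
        raise InvalidParameterError("xmax must exceed xmin")
    v = _values(sample)
    tail = v[v >= xmin]
    if tail.size < min_tail_size:
        raise InsufficientDataError(
            f"tail has {tail.size} values >= xmin; need {min_tail_size}"
        )
    logs = np.log(tail / xmin)
    total = logs.sum()
    if total == 0:
        raise DegenerateSampleError("all tail values equal xmin; estimator diverges")
    if xmax is None:
        shape = 1.0 + tail.size / total
    else:
        shape = 1.0 + _solve_truncated_shape(float(logs.mean()), float(np.log(xmax / xmin)))
    fit = PowerLawFit(alpha=-shape, xmin=float(xmin), n_tail=int(tail.size),
                      ks_stat=np.nan, xmax=xmax)
    ks = _ks_tail(np.sort(tail), fit)
    return PowerLawFit(alpha=-shape, xmin=float(xmin), n_tail=int(tail.size),
                       ks_stat=ks, xmax=xmax)


def _xmin_candidates(v: np.ndarray, max_candidates: int) -> np.ndarray:
    distinct = np.unique(v)
    if distinct.size <= max_candidates:
        return distinct
    idx = np.unique(np.linspace(0, distinct.size - 1, max_candidates).astype(int))
    return distinct[idx]


def select_xmin(
    sample: InterEventSample | np.ndarray,
    xmax: float | None = None,
    min_tail_size: int = DEFAULT_MIN_TAIL_SIZE,
    max_candidates: int = DEFAULT_MAX_XMIN_CANDIDATES,
) -> PowerLawFit:
    """Choose ``xmin`` by KS minimization over candidate sample values.

    Candidates are the distinct values (quantile-thinned to at most
    ``max_candidates``); each candidate leaving a tail of at least
    ``min_tail_size`` is fitted by :func:`mle_shape`, and the fit with the
    smallest KS distance wins (ties go to the smallest ``xmin``).
    """
    v = _values(sample)
    if v.size < min_tail_size:
        raise InsufficientDataError(
            f"sample of {v.size} values; need at least {min_tail_size}"
        )
    best: PowerLawFit | None = None
    for cand in _xmin_candidates(v, max_candidates):
        if xmax is not None and cand >= xmax:
            break
        try:
            fit = mle_shape(v, xmin=float(cand), xmax=xmax, min_tail_size=min_tail_size)
        except (InsufficientDataError, DegenerateSampleError):
            continue
        if best is None or fit.ks_stat < best.ks_stat:
            best = fit
    if best is None:
        raise InsufficientDataError("no xmin candidate leaves a valid tail")
    return best


def _sample_fitted_tail(rng: np.random.Generator, fit: PowerLawFit, n: int) -> np.ndarray:
    b = fit.shape - 1.0
    u = rng.random(n)
    if fit.xmax is None:
        return fit.xmin * (1.0 - u) ** (-1.0 / b)
    s = (fit.xmax / fit.xmin) ** (-b)
    return fit.xmin * (1.0 - u * (1.0 - s)) ** (-1.0 / b)


def gof_bootstrap(
    sample: InterEventSample | np.ndarray,
    fit: PowerLawFit,
    test: str = "KS",
    n_boot: int = 1000,
    seed: int = 0,
    refit_xmin: bool = False,
) -> GOFResult:
    """Semiparametric bootstrap p-value for the Pareto tail hypothesis.

    Each synthetic dataset keeps the observed tail/body split in
    expectation: values land in the tail with probability ``n_tail/n`` and
    are then drawn from the fitted model, otherwise they are resampled from
    the empirical sub-``xmin`` data. Each replicate is refitted (shape only
    at the observed ``xmin`` by default; full xmin re-selection with
    ``refit_xmin=True``) and its statistic computed; the p-value is the
    fraction of replicates with a statistic at least as extreme as observed.
    The hypothesis is accepted at the 5% level iff p ≥ 0.05.
    """
    if n_boot <= 0:
        raise InvalidParameterError("n_boot must be positive")
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} gives a coarse p-value", stacklevel=2)
    test = test.upper()
    if test not in {"KS", "AD"}:
        raise InvalidParameterError("test must be 'KS' or 'AD'")
    stat_fn = _ks_tail if test == "KS" else _ad_tail

    v = _values(sample)
    tail = np.sort(v[v >= fit.xmin])
    body = v[v < fit.xmin]
    n = v.size
    p_tail = tail.size / n
    observed = stat_fn(tail, fit)

    rng = np.random.default_rng(seed)
    exceed = 0
    min_tail = min(DEFAULT_MIN_TAIL_SIZE, max(3, tail.size // 2))
    for _ in range(n_boot):
        n_tail_b = int(rng.binomial(n, p_tail)) if body.size else n
        synth_tail = _sample_fitted_tail(rng, fit, n_tail_b)
        if body.size:
            synth = np.concatenate([synth_tail, rng.choice(body, size=n - n_tail_b)])
        else:
            synth = synth_tail
        try:
            if refit_xmin:
                fit_b = select_xmin(synth, xmax=fit.xmax, min_tail_size=min_tail)
            else:
                fit_b = mle_shape(synth, xmin=fit.xmin, xmax=fit.xmax, min_tail_size=min_tail)
        except (InsufficientDataError, DegenerateSampleError):
            exceed += 1  # an unfittable replicate counts against the model
            continue
        tail_b = np.sort(synth[synth >= fit_b.xmin])
        if stat_fn(tail_b, fit_b) >= observed:
            exceed += 1
    p = exceed / n_boot
    return GOFResult(
        test=test, statistic=observed, p_value=p,
        accepted_at_5pct=bool(p >= 0.05), n_boot=n_boot, seed=seed,
    )


def window_exponents(
    windowed: WindowedInterEvents,
    policy: FitPolicy = FitPolicy(),
    editor_id: str = "",
) -> ExponentSummary:
    """Fit one Pareto exponent per retained hour window.

    Windows whose tail is too small or degenerate are recorded as skipped,
    mirroring how low-statistics hours are excluded from the analysis.
    """
    hours: list[int] = []
    alphas: list[float] = []
    ses: list[float] = []
    skipped: list[int] = []
    fits: dict[int, PowerLawFit] = {}
    for h in windowed.retained_hours:
        values = windowed.samples[h].values
        try:
            if policy.fixed_xmin is not None:
                fit = mle_shape(values, xmin=policy.fixed_xmin, xmax=policy.xmax,
                                min_tail_size=policy.min_tail_size)
            else:
                fit = select_xmin(values, xmax=policy.xmax,
                                  min_tail_size=policy.min_tail_size,
                                  max_candidates=policy.max_candidates)
        except (InsufficientDataError, DegenerateSampleError) as exc:
            logger.info("window %d skipped for %s: %s", h, editor_id or "editor", exc)
            skipped.append(h)
            continue
        hours.append(h)
        alphas.append(fit.alpha)
        # SE from the observed information (variance of ln x in the tail),
        # valid for both the plain and truncated estimators
        tail = values[values >= fit.xmin]
        var_log = float(np.var(np.log(tail))) if tail.size > 1 else np.nan
        ses.append(1.0 / np.sqrt(tail.size * var_log) if var_log > 0 else np.nan)
        fits[h] = fit
    if not hours:
        raise InsufficientDataError(f"no fittable windows for {editor_id or 'editor'}")
    return ExponentSummary(
        editor_id=editor_id, hours=hours,
        window_alphas=np.asarray(alphas), window_ses=np.asarray(ses),
        skipped_hours=skipped, fits=fits,
    )


def population_summary(summaries: list[ExponentSummary]) -> PopulationSummary:
    """Pool relative deviations across editors and moment-match a normal."""
    if not summaries:
        raise InsufficientDataError("no exponent summaries to pool")
    pooled = np.concatenate([s.rel_devs for s in summaries])
    mean_alphas = np.array([s.mean_alpha for s in summaries])
    sd = float(np.std(pooled, ddof=1)) if pooled.size > 1 else 0.0
    return PopulationSummary(
        mean_alphas=mean_alphas,
        pooled_rel_devs=pooled,
        normal_fit=(float(np.mean(pooled)), sd),
    )
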