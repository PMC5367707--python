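"""Burstiness and memory coefficients of an inter-event sequence.

Two scalar signatures of non-Poissonian activity:

* burstiness ``B = (σ − μ)/(σ + μ)`` with the population standard deviation
  σ and mean μ of the inter-event times: −1 for a perfectly periodic
  sequence, 0 for a Poisson process, →1 for extremely bursty trains;
* memory ``M``: the Pearson correlation between consecutive inter-event
  times (τ₁..τ_{n−1} against τ₂..τ_n), 0 for iid gaps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateSampleError, InsufficientDataError
from .interevent import InterEventSample


@dataclass(frozen=True)
class BMStats:
    B: float
    M: float | None
    n: int


def burstiness(sample: InterEventSample) -> float:
    """(σ − μ)/(σ + μ), population σ; in [−1, 1), −1 iff all gaps equal."""
    if len(sample) < 2:
        raise InsufficientDataError("burstiness needs at least 2 inter-event times")
    v = sample.values
    mu = float(np.mean(v))
    sigma = float(np.std(v))  # population convention
    return (sigma - mu) / (sigma + mu)


def memory(sample: InterEventSample) -> float:
    """Lag-1 Pearson correlation of the inter-event sequence."""
    if len(sample) < 3:
        raise InsufficientDataError("memory needs at least 3 inter-event times")
    v = sample.values
    a, b = v[:-1], v[1:]
    if np.std(a) == 0 or np.std(b) == 0:
        raise DegenerateSampleError("memory undefined for zero-variance subsequences")
    return float(stats.pearsonr(a, b).statistic)


def compute_bm(sample: InterEventSample) -> BMStats:
    """Both coefficients; M is None when undefined (degenerate gaps)."""
    B = burstiness(sample)
    try:
        M = memory(sample)
    except (DegenerateSampleError, InsufficientDataError):
        M = None
    return BMStats(B=B, M=M, n=len(sample))
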