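"""Pairwise two-sample Kolmogorov–Smirnov distances between hour windows.

The stationarity claim is visual as well as statistical: if the conditional
inter-event distribution does not depend on the hour of day, the K-S
distance (the supremum gap between two empirical CCDFs — identical to the
gap between the CDFs) between any two retained one-hour windows should be
small, comparable to the two-sample sampling null. The module reports the
distances themselves; the matrix marks pairs involving a non-retained
window as undefined (``NaN``, serialized ``NA``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError
from .interevent import InterEventSample, WindowedInterEvents


@dataclass(frozen=True)
class KSMatrix:
    """Symmetric 24×24 distance matrix; NaN where a window is not retained."""

    values: np.ndarray
    retained_mask: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "retained_mask", np.asarray(self.retained_mask, dtype=bool))

    def max_offdiagonal(self) -> float:
        hours = np.flatnonzero(self.retained_mask)
        best = 0.0
        for i in hours:
            for j in hours:
                if i < j:
                    best = max(best, self.values[i, j])
        return best

    def to_frame(self) -> pd.DataFrame:
        labels = [f"{h:02d}" for h in range(24)]
        return pd.DataFrame(self.values, index=labels, columns=labels)

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i in range(24):
            for j in range(i + 1, 24):
                if self.retained_mask[i] and self.retained_mask[j]:
                    rows.append({"hour_i": i, "hour_j": j, "ks_distance": self.values[i, j]})
        return pd.DataFrame(rows, columns=["hour_i", "hour_j", "ks_distance"])


def ks_distance(a: InterEventSample, b: InterEventSample) -> float:
    """Classical two-sample KS statistic: sup |ECDF_a − ECDF_b|."""
    if len(a) == 0 or len(b) == 0:
        raise InsufficientDataError("both samples must be non-empty")
    return float(stats.ks_2samp(a.values, b.values, method="asymp").statistic)


def ks_pvalue(a: InterEventSample, b: InterEventSample) -> float:
    """Optional diagnostic: asymptotic two-sample KS p-value."""
    if len(a) == 0 or len(b) == 0:
        raise InsufficientDataError("both samples must be non-empty")
    return float(stats.ks_2samp(a.values, b.values, method="asymp").pvalue)


def pairwise_matrix(windowed: WindowedInterEvents) -> KSMatrix:
    """All pairwise distances among retained hour windows."""
    hours = windowed.retained_hours
    if len(hours) < 2:
        raise InsufficientDataError("need at least 2 retained windows")
    values = np.full((24, 24), np.nan)
    for i in hours:
        values[i, i] = 0.0
    for k, i in enumerate(hours):
        for j in hours[k + 1:]:
            d = ks_distance(windowed.samples[i], windowed.samples[j])
            values[i, j] = d
            values[j, i] = d
    return KSMatrix(values=values, retained_mask=windowed.retained_mask)


def write_matrix_tsv(matrix: KSMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", na_rep="NA", float_format="%.6f")
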