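"""Arsenic exposure handling.

Whole-blood arsenic in this kind of biomonitoring cohort is approximately
lognormal, so all summaries live on the natural-log scale: the geometric mean
is ``exp(mean(ln v))`` and the extreme-group boundaries are the geometric mean
divided/multiplied by the geometric standard deviation, i.e. ``exp(mean +- sd)``
of the log values.  Values censored below the assay's limit of detection (LOD)
are substituted by LOD/2 before any log-scale computation.

The ``low`` / ``median`` / ``high`` partition produced here drives both the
extreme-group transcriptome screen (high vs low) and the dichotomous
``high`` vs ``median-or-low`` exposure contrast used by the mediation cascade.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationResult",
    "ExposureClassing",
    "classify_exposure",
    "impute_below_lod",
    "log_pearson_correlation",
]


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation of ln-transformed paired values."""

    r: float
    p: float
    n: int
    n_dropped: int = 0


@dataclass
class ExposureClassing:
    """Low/median/high exposure labels plus the statistics that produced them.

    Thresholds are multiplicative: ``low_threshold = geomean / exp(log_sd)``
    and ``high_threshold = geomean * exp(log_sd)``.  A value strictly above the
    high threshold is ``high``, strictly below the low threshold is ``low``,
    everything else (ties included) is ``median``.
    """

    labels: pd.Series
    low_threshold: float
    high_threshold: float
    geomean: float
    log_sd: float
    iqr: float

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def counts(self) -> dict:
        c = self.labels.value_counts()
        return {k: int(c.get(k, 0)) for k in ("low", "median", "high")}

    def high_vs_rest(self) -> pd.Series:
        """Dichotomous grouping for mediation: high vs median-or-low."""
        return (self.labels == "high").rename("high_as")

    def summary(self) -> dict:
        return {
            "geomean_ugL": self.geomean,
            "log_sd": self.log_sd,
            "low_threshold_ugL": self.low_threshold,
            "high_threshold_ugL": self.high_threshold,
            "iqr_ugL": self.iqr,
            "counts": self.counts,
        }


def impute_below_lod(values, lod: float, below_lod=None) -> np.ndarray:
    """Substitute censored measurements by half the limit of detection.

    Parameters
    ----------
    values : array-like
        Measured concentrations (ug/L).
    lod : float
        Limit of detection (ug/L); must be positive.
    below_lod : array-like of bool, optional
        Censoring flags.  If omitted, every value strictly below ``lod`` is
        treated as censored.  The operation is idempotent either way because
        ``lod/2 < lod``.
    """
    if lod <= 0:
        raise ValueError(f"lod must be positive, got {lod}")
    v = np.asarray(values, dtype=float).copy()
    if below_lod is None:
        mask = v < lod
    else:
        mask = np.asarray(below_lod, dtype=bool)
        if mask.shape != v.shape:
            raise ValueError("below_lod flags must match values in length")
    v[mask] = lod / 2.0
    return v


def classify_exposure(values) -> ExposureClassing:
    """Partition exposures into low / median / high extreme groups.

    Boundaries are the geometric mean divided/multiplied by the geometric SD
    (sample SD of the log values, n-1 denominator).  The IQR is computed on
    the raw scale with the linear-interpolation (type-7) quantile convention.
    """
    if isinstance(values, pd.Series):
        index = values.index
        v = values.to_numpy(dtype=float)
    else:
        v = np.asarray(values, dtype=float)
        index = pd.RangeIndex(len(v))
    if v.ndim != 1 or len(v) < 3:
        raise ValueError("classify_exposure needs at least 3 values")
    if not np.all(np.isfinite(v)) or np.any(v <= 0):
        raise ValueError("all exposure values must be positive and finite")

    log_v = np.log(v)
    mu = float(np.mean(log_v))
    sd = float(np.std(log_v, ddof=1))
    geomean = float(np.exp(mu))
    low_thr = float(np.exp(mu - sd))
    high_thr = float(np.exp(mu + sd))

    labels = np.full(len(v), "median", dtype=object)
    labels[v < low_thr] = "low"
    labels[v > high_thr] = "high"

    q25, q75 = np.quantile(v, [0.25, 0.75])  # type-7 / linear interpolation
    return ExposureClassing(
        labels=pd.Series(labels, index=index, name="as_class"),
        low_threshold=low_thr,
        high_threshold=high_thr,
        geomean=geomean,
        log_sd=sd,
        iqr=float(q75 - q25),
    )


def log_pearson_correlation(x, y) -> CorrelationResult:
    """Pearson correlation between the natural logarithms of paired values.

    Pairs in which either member is missing (NaN) are dropped and counted in
    ``n_dropped``.  The two-sided p-value comes from the t transform of r with
    n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired (equal length)")
    keep = np.isfinite(x) & np.isfinite(y)
    n_dropped = int(len(x) - keep.sum())
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("values must be positive for log transformation")
    res = stats.pearsonr(np.log(x), np.log(y))
    return CorrelationResult(
        r=float(res.statistic), p=float(res.pvalue), n=len(x), n_dropped=n_dropped
    )
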