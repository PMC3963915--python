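"""Birth-outcome derivations: SGA status and GA-adjusted birth-weight extremes.

Two derived outcomes feed the downstream screens:

* **SGA** (small for gestational age): birth weight strictly below the
  sex-specific 10th percentile for the completed gestational week, looked up
  in an externally supplied (or synthetically derived) reference curve table.
  No interpolation: curves are per completed week, and a missing (sex, week)
  entry is an error.

* **GA-adjusted birth-weight ratio**: birth weight divided by the value
  predicted from a per-sex ordinary least squares fit of weight on gestational
  age with a quadratic term.  The log of that ratio is thresholded at its
  within-sex mean +- SD to define ``low`` / ``mid`` / ``high`` birth-weight
  extreme groups for the transcriptome screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GrowthCurveTable",
    "AdjustedBirthWeight",
    "MissingCurveError",
    "classify_sga",
    "classify_sga_cohort",
    "fit_ga_adjustment",
]

SEXES = ("boy", "girl")


class MissingCurveError(KeyError):
    """Raised when a (sex, gestational week) pair has no reference entry."""


@dataclass
class GrowthCurveTable:
    """Sex-specific 10th-percentile birth-weight reference curves.

    ``table`` has columns ``sex``, ``ga_weeks`` (completed weeks, int) and
    ``p10_g``; each (sex, week) pair appears exactly once and p10 is
    non-decreasing in week within sex.
    """

    table: pd.DataFrame
    _lookup: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        required = {"sex", "ga_weeks", "p10_g"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"growth curve table missing columns: {sorted(missing)}")
        t = self.table
        if t.duplicated(["sex", "ga_weeks"]).any():
            raise ValueError("duplicate (sex, week) entries in growth curves")
        for sex, grp in t.groupby("sex"):
            p10 = grp.sort_values("ga_weeks")["p10_g"].to_numpy()
            if np.any(np.diff(p10) < 0):
                raise ValueError(f"p10 not monotone non-decreasing for {sex}")
        self._lookup = {
            (row.sex, int(row.ga_weeks)): float(row.p10_g) for row in t.itertuples()
        }

    def p10(self, sex: str, ga_weeks: int) -> float:
        try:
            return self._lookup[(sex, int(ga_weeks))]
        except KeyError:
            raise MissingCurveError(
                f"no reference curve entry for sex={sex!r}, week={ga_weeks}"
            ) from None

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "GrowthCurveTable":
        return cls(pd.read_csv(path))


def classify_sga(bw_g: float, ga_weeks: int, sex: str, curves: GrowthCurveTable) -> bool:
    """True iff birth weight is strictly below the sex/week 10th percentile."""
    return bool(bw_g < curves.p10(sex, ga_weeks))


def classify_sga_cohort(cohort: pd.DataFrame, curves: GrowthCurveTable) -> pd.Series:
    """Vectorised SGA labels for a cohort table.

    Rows with missing birth weight or gestational age get ``pd.NA``.
    """
    out = pd.Series(pd.NA, index=cohort.index, dtype="boolean", name="sga")
    ok = cohort["birth_weight_g"].notna() & cohort["ga_weeks"].notna()
    for idx in cohort.index[ok]:
        row = cohort.loc[idx]
        out.loc[idx] = classify_sga(
            float(row["birth_weight_g"]), int(row["ga_weeks"]), row["sex"], curves
        )
    return out


@dataclass
class AdjustedBirthWeight:
    """Observed/expected birth-weight ratios and their extreme groups.

    ``table`` is indexed like the cohort and carries ``expected_g``, ``ratio``,
    ``ln_ratio`` and ``bw_extreme`` (``low``/``mid``/``high``/``missing``).
    ``coefficients`` maps sex -> (intercept, linear, quadratic) of the per-sex
    OLS fit of birth weight on gestational age; ``thresholds`` maps sex ->
    (mean - sd, mean + sd) of the within-sex ln-ratio distribution.
    """

    table: pd.DataFrame
    coefficients: dict
    thresholds: dict
    n_excluded: int

    @property
    def extreme_counts(self) -> dict:
        out = {}
        for sex in self.coefficients:
            lab = self.table.loc[self.table["sex"] == sex, "bw_extreme"]
            out[sex] = {
                "low": int((lab == "low").sum()),
                "high": int((lab == "high").sum()),
            }
        return out


def _fit_quadratic(ga: np.ndarray, bw: np.ndarray) -> np.ndarray:
    # Least squares on [1, ga, ga^2]; centering ga improves conditioning and
    # the returned coefficients are mapped back to the raw-GA parametrisation.
    c = ga.mean()
    g = ga - c
    X = np.column_stack([np.ones_like(g), g, g * g])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("singular design: gestational age lacks variation")
    beta_c, *_ = np.linalg.lstsq(X, bw, rcond=None)
    b0, b1, b2 = beta_c
    # f(ga) = b0 + b1 (ga-c) + b2 (ga-c)^2
    return np.array([b0 - b1 * c + b2 * c * c, b1 - 2.0 * b2 * c, b2])


def fit_ga_adjustment(cohort: pd.DataFrame) -> AdjustedBirthWeight:
    """Per-sex quadratic regression of birth weight on gestational age.

    For each subject the expected weight is the fitted value at their GA, the
    ratio observed/expected is logged, and ``low``/``high`` extreme labels are
    assigned below/above the within-sex mean -+ SD of the log ratio (strict
    inequalities; boundary values stay ``mid``).  Subjects with missing birth
    weight or GA are excluded from fitting and labelled ``missing``.
    """
    required = {"sex", "ga_weeks", "birth_weight_g"}
    missing_cols = required - set(cohort.columns)
    if missing_cols:
        raise ValueError(f"cohort missing columns: {sorted(missing_cols)}")

    complete = cohort["birth_weight_g"].notna() & cohort["ga_weeks"].notna()
    n_excluded = int((~complete).sum())

    table = pd.DataFrame(index=cohort.index)
    table["sex"] = cohort["sex"]
    table["expected_g"] = np.nan
    table["ratio"] = np.nan
    table["ln_ratio"] = np.nan
    table["bw_extreme"] = "missing"

    coefficients: dict = {}
    thresholds: dict = {}
    for sex, grp in cohort.loc[complete].groupby("sex"):
        if len(grp) < 6:
            raise ValueError(f"need at least 6 complete subjects per sex, {sex} has {len(grp)}")
        ga = grp["ga_weeks"].to_numpy(dtype=float)
        bw = grp["birth_weight_g"].to_numpy(dtype=float)
        beta = _fit_quadratic(ga, bw)
        coefficients[sex] = tuple(float(b) for b in beta)
        expected = beta[0] + beta[1] * ga + beta[2] * ga * ga
        if np.any(expected <= 0):
            raise ValueError(f"non-positive expected birth weight in {sex} fit")
        ratio = bw / expected
        # the log ratio is only defined for positive weights; anything else is
        # invalid data and treated like missing
        valid = ratio > 0
        n_excluded += int((~valid).sum())
        ln_ratio = np.where(valid, np.log(np.where(valid, ratio, 1.0)), np.nan)
        m = float(np.mean(ln_ratio[valid]))
        s = float(np.std(ln_ratio[valid], ddof=1))
        thresholds[sex] = (m - s, m + s)
        labels = np.full(len(grp), "mid", dtype=object)
        labels[~valid] = "missing"
        # a spread at floating-point noise level means a perfect fit: no extremes
        if s > 1e-10:
            labels[valid & (ln_ratio < m - s)] = "low"
            labels[valid & (ln_ratio > m + s)] = "high"
        table.loc[grp.index, "expected_g"] = expected
        table.loc[grp.index, "ratio"] = ratio
        table.loc[grp.index, "ln_ratio"] = ln_ratio
        table.loc[grp.index, "bw_extreme"] = labels

    return AdjustedBirthWeight(
        table=table,
        coefficients=coefficients,
        thresholds=thresholds,
        n_excluded=n_excluded,
    )
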