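"""Microarray preprocessing and the sex-stratified dual-contrast quadrant screen.

The expression container emulates single-channel (Cy3) feature-extraction
output: a log2 intensity matrix (features x samples), five boolean reliability
flags per feature x sample (above feature noise, below saturation, not a
population outlier, uniform spot, background not an outlier), and a feature
annotation mapping probes to transcript accessions, gene symbols and named
gene panels.

Preprocessing follows the standard single-colour pipeline: log2 transform
(inputs here are already log2), between-array quantile normalization,
averaging of probes that interrogate the same transcript sequence, and a
reliability filter that keeps only features whose five flags all pass in every
sample entering a given contrast.

The screen itself contrasts extreme exposure groups (high vs low arsenic) and
extreme gestational-age-adjusted birth-weight groups (low vs high) within one
sex, gene by gene, with Welch's unequal-variance t-test.  Genes are placed in
quadrants by the signs of the two mean differences; quadrant 1 (up with
exposure, up with growth restriction) and quadrant 3 (down with both) are the
mediator-candidate quadrants.  Per the targeted-panel design, p-values are not
corrected for multiple testing; Benjamini-Hochberg q-values are emitted as an
advisory column only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FLAG_NAMES",
    "ExpressionMatrix",
    "SchemaError",
    "ScreenError",
    "WelchResult",
    "QuadrantScreenResult",
    "read_expression",
    "write_expression",
    "quantile_normalize",
    "collapse_replicates",
    "reliability_filter",
    "welch_t",
    "welch_t_arrays",
    "quadrant_screen",
]

FLAG_NAMES = (
    "above_noise",
    "below_saturation",
    "not_population_outlier",
    "spot_uniform",
    "background_not_outlier",
)

#: floor applied to p-values before taking -log10 for plot data
P_FLOOR = np.finfo(float).tiny


class SchemaError(ValueError):
    """A table does not conform to the expected expression-data schema."""


class ScreenError(ValueError):
    """A contrast group is empty or otherwise unusable for screening."""


@dataclass
class ExpressionMatrix:
    """Log2 expression values with reliability flags and probe annotation.

    ``values``: DataFrame, features x samples (index = probe or transcript id).
    ``flags``: dict mapping each of the five flag names to a boolean DataFrame
    aligned with ``values`` (True = criterion passed).
    ``annotation``: DataFrame indexed like ``values`` with at least
    ``gene_symbol``, ``transcript`` and ``panels`` (semicolon-separated panel
    names) columns.
    """

    values: pd.DataFrame
    flags: dict
    annotation: pd.DataFrame

    def __post_init__(self) -> None:
        if set(self.flags) != set(FLAG_NAMES):
            missing = set(FLAG_NAMES) - set(self.flags)
            extra = set(self.flags) - set(FLAG_NAMES)
            raise SchemaError(f"flag tables mismatch: missing={sorted(missing)}, unexpected={sorted(extra)}")
        if not self.values.index.is_unique:
            raise SchemaError("duplicate feature ids in expression matrix")
        for name, f in self.flags.items():
            if not (f.index.equals(self.values.index) and f.columns.equals(self.values.columns)):
                raise SchemaError(f"flag table {name!r} not aligned with values")
        if not self.annotation.index.equals(self.values.index):
            raise SchemaError("annotation not aligned with values")
        for col in ("gene_symbol", "transcript", "panels"):
            if col not in self.annotation.columns:
                raise SchemaError(f"annotation missing column {col!r}")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def reliable(self) -> pd.DataFrame:
        """Boolean DataFrame: all five criteria pass for feature x sample."""
        out = self.flags[FLAG_NAMES[0]].copy()
        for name in FLAG_NAMES[1:]:
            out &= self.flags[name]
        return out

    def panel_features(self, panel: str) -> pd.Index:
        sets = self.annotation["panels"].str.split(";")
        mask = sets.map(lambda ps: panel in ps)
        return self.values.index[mask]

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values.copy(),
            flags={k: v.copy() for k, v in self.flags.items()},
            annotation=self.annotation.copy(),
        )


def write_expression(matrix: ExpressionMatrix, outdir) -> dict:
    """Write values/flags/annotation TSVs; returns the paths used."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "values": outdir / "expression_log2.tsv",
        "flags": outdir / "expression_flags.tsv",
        "annotation": outdir / "expression_annotation.tsv",
    }
    matrix.values.rename_axis("feature_id").to_csv(paths["values"], sep="\t")
    long = []
    for name in FLAG_NAMES:
        f = matrix.flags[name].stack()
        f.name = name
        long.append(f)
    flags = pd.concat(long, axis=1).rename_axis(["feature_id", "sample_id"]).astype(int)
    flags.to_csv(paths["flags"], sep="\t")
    matrix.annotation.rename_axis("feature_id").to_csv(paths["annotation"], sep="\t")
    return paths


def read_expression(values_path, flags_path, annotation_path) -> ExpressionMatrix:
    """Load an expression matrix from the three-TSV on-disk layout.

    Raises :class:`SchemaError` naming any missing flag column, and on
    duplicate (feature, sample) cells or non-numeric intensities.
    """
    values = pd.read_csv(values_path, sep="\t", index_col="feature_id")
    values.index.name = None
    if not values.index.is_unique:
        raise SchemaError("duplicate feature ids in values table")
    try:
        values = values.astype(float)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"non-numeric intensity in values table: {exc}") from exc

    flags_long = pd.read_csv(flags_path, sep="\t")
    for col in ("feature_id", "sample_id", *FLAG_NAMES):
        if col not in flags_long.columns:
            raise SchemaError(f"flags table missing column {col!r}")
    if flags_long.duplicated(["feature_id", "sample_id"]).any():
        raise SchemaError("duplicate (feature, sample) cells in flags table")
    flags = {}
    for name in FLAG_NAMES:
        wide = flags_long.pivot(index="feature_id", columns="sample_id", values=name)
        wide = wide.reindex(index=values.index, columns=values.columns)
        if wide.isna().any().any():
            raise SchemaError(f"flags table does not cover every (feature, sample) for {name!r}")
        flags[name] = wide.astype(bool)
        flags[name].columns.name = None
        flags[name].index.name = None
    annotation = pd.read_csv(annotation_path, sep="\t", index_col="feature_id")
    annotation.index.name = None
    unmatched = annotation.index.symmetric_difference(values.index)
    if len(unmatched):
        raise SchemaError(f"annotation/values feature ids differ, e.g. {list(unmatched[:5])}")
    annotation = annotation.reindex(values.index)
    return ExpressionMatrix(values=values, flags=flags, annotation=annotation)


def _quantile_normalize_frame(df: pd.DataFrame) -> pd.DataFrame:
    X = df.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    if not np.all(np.isfinite(X)):
        raise ValueError("missing or non-finite values must be handled before normalization")
    n = X.shape[0]
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(n)
        assigned[order] = ref
        # ties receive the mean of the reference quantiles at their tied ranks
        out[:, j] = pd.Series(assigned).groupby(col, sort=False).transform("mean").to_numpy()
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def quantile_normalize(data):
    """Between-array quantile normalization of log2 intensities.

    Every sample's sorted intensity vector is replaced by the across-sample
    mean of order statistics; tied intensities within a sample receive the
    mean of the reference quantiles at their tied ranks.  Accepts and returns
    either a DataFrame or an :class:`ExpressionMatrix` (flags and annotation
    pass through unchanged).
    """
    if isinstance(data, ExpressionMatrix):
        out = data.copy()
        out.values = _quantile_normalize_frame(data.values)
        return out
    return _quantile_normalize_frame(data)


def collapse_replicates(matrix: ExpressionMatrix, mapping: pd.Series | None = None) -> ExpressionMatrix:
    """Average replicate probes of the same sequence; re-key by transcript.

    ``mapping`` (feature id -> replicate group key) defaults to the
    annotation's ``transcript`` column.  Log2 values are averaged within each
    group; reliability flags combine conservatively (a collapsed feature is
    reliable in a sample only if every replicate probe is).
    """
    if mapping is None:
        mapping = matrix.annotation["transcript"]
    mapping = mapping.reindex(matrix.values.index)
    if mapping.isna().any():
        raise ValueError("replicate mapping does not cover every feature")
    values = matrix.values.groupby(mapping).mean()
    flags = {name: f.groupby(mapping).all() for name, f in matrix.flags.items()}
    ann = matrix.annotation.groupby(mapping).first()
    ann["n_probes"] = matrix.annotation.groupby(mapping).size()
    values.index.name = None
    ann.index.name = None
    for f in flags.values():
        f.index.name = None
    return ExpressionMatrix(values=values, flags=flags, annotation=ann)


def reliability_filter(matrix: ExpressionMatrix, samples: Sequence) -> tuple:
    """Features whose five flags all pass in every sample of ``samples``.

    Returns ``(kept_index, report)`` where the report carries the in/out
    counts at sequence and gene-symbol level.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("sample subset must be nonempty")
    rel = matrix.reliable()[samples].all(axis=1)
    kept = matrix.values.index[rel]
    report = {
        "n_features_in": int(matrix.n_features),
        "n_features_kept": int(rel.sum()),
        "n_genes_in": int(matrix.annotation["gene_symbol"].nunique()),
        "n_genes_kept": int(matrix.annotation.loc[kept, "gene_symbol"].nunique()),
    }
    return kept, report


class WelchResult(NamedTuple):
    t: float
    df: float
    p: float
    mean_diff: float


def welch_t_arrays(a: np.ndarray, b: np.ndarray, axis: int = -1):
    """Vectorised Welch t-test along ``axis``; returns (t, df, p, mean_diff).

    Degenerate rows (zero pooled variance) get t=0, p=1 when the means are
    equal, and p floored at machine tiny when they differ; a warning is
    emitted because such features carry no usable variance information.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape[axis] < 2 or b.shape[axis] < 2:
        raise ValueError("each group needs at least 2 values")
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # degenerate (near-)zero-variance contrasts are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=axis, equal_var=False)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    df = np.asarray(res.df, dtype=float)
    diff = np.asarray(a.mean(axis=axis) - b.mean(axis=axis), dtype=float)
    bad = ~np.isfinite(t)
    if np.any(bad):
        warnings.warn("zero-variance contrast encountered; p set to 1 (equal means) or floored", RuntimeWarning)
        zero_diff = np.isclose(diff, 0.0)
        sign = np.where(diff >= 0, 1.0, -1.0)
        t = np.where(bad, np.where(zero_diff, 0.0, np.inf * sign), t)
        p = np.where(bad, np.where(zero_diff, 1.0, P_FLOOR), p)
        df = np.where(bad, a.shape[axis] + b.shape[axis] - 2.0, df)
    return t, df, p, diff


def welch_t(group_a, group_b) -> WelchResult:
    """Welch's unequal-variance two-sample t-test (two-sided).

    Returns the t statistic, Satterthwaite degrees of freedom, two-sided
    p-value and the mean difference ``mean(a) - mean(b)``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.ndim != 1 or b.ndim != 1:
        raise ValueError("groups must be 1-dimensional")
    t, df, p, diff = welch_t_arrays(a, b, axis=0)
    return WelchResult(float(t), float(df), float(p), float(diff))


@dataclass
class QuadrantScreenResult:
    """Per-sequence dual-contrast statistics and quadrant assignments.

    ``table`` columns: ``gene`` (symbol), ``d_as``/``p_as`` (high minus low
    arsenic mean log2 difference and Welch p), ``d_bw``/``p_bw`` (low minus
    high adjusted-birth-weight difference and Welch p), ``quadrant`` (1-4),
    ``candidate`` (concordant quadrant 1/3 with both p < alpha), ``labelled``
    (either p < alpha, the plot-annotation rule), advisory ``q_as``/``q_bw``
    Benjamini-Hochberg values, and ``neglog10_p_as``/``neglog10_p_bw`` plot
    coordinates (p floored at machine tiny).
    """

    table: pd.DataFrame
    stratum: str
    panel: str | None
    alpha: float
    group_sizes: dict
    filter_report: dict

    @property
    def candidates(self) -> pd.DataFrame:
        return self.table[self.table["candidate"]]


def _quadrant(d_as: np.ndarray, d_bw: np.ndarray) -> np.ndarray:
    q = np.full(len(d_as), 4, dtype=int)
    q[(d_as > 0) & (d_bw > 0)] = 1
    q[(d_as <= 0) & (d_bw >= 0)] = 2
    q[(d_as < 0) & (d_bw < 0)] = 3
    return q


def quadrant_screen(
    matrix: ExpressionMatrix,
    exposure_labels: pd.Series,
    bw_labels: pd.Series,
    sex_labels: pd.Series,
    stratum: str,
    panel: str | None = None,
    alpha: float = 0.05,
) -> QuadrantScreenResult:
    """Sex-stratified dual-contrast extreme-group screen.

    Within the ``stratum`` sex, each surviving feature is tested (Welch,
    two-sided) for high-vs-low arsenic and for low-vs-high adjusted birth
    weight.  Differences are oriented as (high - low arsenic) and (low - high
    birth weight), so quadrant 1 collects transcripts up-regulated with both
    exposure and growth restriction and quadrant 3 those down-regulated with
    both.  Features are restricted to ``panel`` members (if given) that pass
    the five reliability criteria in every sample of the union of the four
    contrast groups.  No multiple-testing correction is applied to the primary
    candidate call; BH q-values are advisory.
    """
    samples = matrix.samples
    for name, s in (("exposure", exposure_labels), ("bw", bw_labels), ("sex", sex_labels)):
        if not samples.isin(s.index).all():
            raise ValueError(f"{name} labels missing for some samples")
    in_sex = samples[sex_labels.reindex(samples) == stratum]
    grp = {
        "as_high": in_sex[exposure_labels.reindex(in_sex) == "high"],
        "as_low": in_sex[exposure_labels.reindex(in_sex) == "low"],
        "bw_low": in_sex[bw_labels.reindex(in_sex) == "low"],
        "bw_high": in_sex[bw_labels.reindex(in_sex) == "high"],
    }
    for name, g in grp.items():
        if len(g) < 2:
            raise ScreenError(f"contrast group {name!r} has {len(g)} samples in stratum {stratum!r}")

    contrast_union = grp["as_high"].union(grp["as_low"]).union(grp["bw_low"]).union(grp["bw_high"])
    features = matrix.panel_features(panel) if panel else matrix.values.index
    sub = ExpressionMatrix(
        values=matrix.values.loc[features],
        flags={k: v.loc[features] for k, v in matrix.flags.items()},
        annotation=matrix.annotation.loc[features],
    )
    kept, report = reliability_filter(sub, contrast_union)
    if len(kept) == 0:
        raise ScreenError("no features survive the reliability filter")
    V = sub.values.loc[kept]

    _, _, p_as, d_as = welch_t_arrays(
        V[grp["as_high"]].to_numpy(), V[grp["as_low"]].to_numpy(), axis=1
    )
    _, _, p_bw, d_bw = welch_t_arrays(
        V[grp["bw_low"]].to_numpy(), V[grp["bw_high"]].to_numpy(), axis=1
    )
    quadrant = _quadrant(d_as, d_bw)
    concordant = (quadrant == 1) | (quadrant == 3)
    candidate = concordant & (p_as < alpha) & (p_bw < alpha)
    labelled = (p_as < alpha) | (p_bw < alpha)
    q_as = multipletests(p_as, method="fdr_bh")[1]
    q_bw = multipletests(p_bw, method="fdr_bh")[1]

    table = pd.DataFrame(
        {
            "gene": sub.annotation.loc[kept, "gene_symbol"].to_numpy(),
            "d_as": d_as,
            "p_as": p_as,
            "d_bw": d_bw,
            "p_bw": p_bw,
            "quadrant": quadrant,
            "candidate": candidate,
            "labelled": labelled,
            "q_as": q_as,
            "q_bw": q_bw,
            "neglog10_p_as": -np.log10(np.maximum(p_as, P_FLOOR)),
            "neglog10_p_bw": -np.log10(np.maximum(p_bw, P_FLOOR)),
        },
        index=kept,
    ).sort_index()

    return QuadrantScreenResult(
        table=table,
        stratum=stratum,
        panel=panel,
        alpha=alpha,
        group_sizes={k: int(len(v)) for k, v in grp.items()},
        filter_report=report,
    )
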