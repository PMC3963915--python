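"""Exposure-outcome regression models with IQR-scaled effects.

Continuous outcomes (birth weight, head circumference) are fitted by ordinary
least squares, binary outcomes (SGA) by maximum-likelihood logistic
regression.  Exposure enters continuously; reported effects are rescaled to
one interquartile-range increase (coefficient x IQR for linear models,
exp(coefficient x IQR) as an odds ratio for logistic models), with Wald
confidence intervals rescaled identically.

The covariate workflow mirrors a common epidemiological recipe: a small set
of a-priori confounders (sex of the newborn, maternal smoking) is always
retained; remaining candidates survive a backward elimination that repeatedly
drops the least significant candidate above p = 0.05 from the full multiple
model.  Effect modification is probed by adding a cross-product term, flagged
at the deliberately liberal p < 0.20, in which case stratified fits are
reported.  Linear-model assumptions are checked formally (Kolmogorov-Smirnov
on standardized residuals, White's general heteroskedasticity test, the
classical pure-error lack-of-fit F-test where the design contains replicated
rows), and models are refitted without influential observations (leverage
> 2p/n or |externally studentized residual| > 3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.diagnostic import het_white
from statsmodels.stats.outliers_influence import OLSInfluence
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "DegenerateDesignError",
    "SeparationError",
    "DiagnosticsRecord",
    "EffectEstimate",
    "InteractionResult",
    "select_covariates",
    "fit_linear_effect",
    "fit_logistic_effect",
    "test_interaction",
    "run_diagnostics",
]


class DegenerateDesignError(ValueError):
    """The design matrix is singular or a model column is constant."""


class SeparationError(RuntimeError):
    """Perfect separation: logistic ML estimates do not exist."""


def build_design(data: pd.DataFrame, columns) -> tuple[pd.DataFrame, dict]:
    """Expand model columns into a numeric design block.

    Object/categorical/boolean columns become 0/1 dummies (first level
    dropped); the returned mapping links each requested column to the design
    columns it produced, so multi-level covariates can be tested jointly.
    """
    X = pd.DataFrame(index=data.index)
    groups: dict = {}
    for col in columns:
        if col not in data.columns:
            raise KeyError(f"model column {col!r} not in data")
        s = data[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            d = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            for c in d.columns:
                X[c] = d[c]
            groups[col] = list(d.columns)
        else:
            X[col] = s.astype(float)
            groups[col] = [col]
    return X, groups


def _complete_cases(data: pd.DataFrame, columns) -> pd.DataFrame:
    return data.dropna(subset=[c for c in columns if c in data.columns])


def _check_constant(X: pd.DataFrame) -> None:
    for c in X.columns:
        if np.nanstd(X[c].to_numpy(dtype=float)) == 0:
            raise DegenerateDesignError(f"model column {c!r} is constant")


def _fit(y: pd.Series, X: pd.DataFrame, family: str):
    Xc = sm.add_constant(X.astype(float), has_constant="add")
    if family == "linear":
        return sm.OLS(y.astype(float), Xc).fit()
    if family == "logistic":
        import warnings

        from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # convergence chatter; checked via mle_retvals below
                warnings.simplefilter("error", PerfectSeparationWarning)
                res = sm.Logit(y.astype(float), Xc).fit(disp=0)
        except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError) as exc:
            raise SeparationError(f"perfect separation detected: {exc}") from exc
        if not res.mle_retvals.get("converged", True) or np.any(np.abs(res.params) > 1e2):
            raise SeparationError("logistic fit did not converge; separation suspected")
        return res
    raise ValueError(f"unknown family {family!r}")


def select_covariates(
    data: pd.DataFrame,
    outcome: str,
    candidates,
    forced,
    family: str = "linear",
    alpha: float = 0.05,
) -> list:
    """Backward elimination keeping forced confounders unconditionally.

    Starting from the full model (forced + all candidates), the candidate
    with the largest Wald p-value above ``alpha`` is dropped and the model
    refitted, until every remaining candidate is significant.  Multi-level
    categorical candidates are tested jointly (Wald test on their dummy
    block).  The drop rule (largest p first) makes the procedure
    deterministic and order-independent.
    """
    forced = list(forced)
    remaining = list(candidates)
    df = _complete_cases(data, [outcome, *forced, *remaining])
    while True:
        X, groups = build_design(df, forced + remaining)
        _check_constant(X)
        res = _fit(df[outcome], X, family)
        if not remaining:
            break
        pvals = {}
        exog_names = list(res.model.exog_names)
        for cand in remaining:
            cols = groups[cand]
            if len(cols) == 1:
                pvals[cand] = float(res.pvalues[cols[0]])
            else:
                R = np.zeros((len(cols), len(exog_names)))
                for i, c in enumerate(cols):
                    R[i, exog_names.index(c)] = 1.0
                pvals[cand] = float(res.wald_test(R, scalar=True).pvalue)
        worst = max(remaining, key=lambda c: (pvals[c], c))
        if pvals[worst] > alpha:
            remaining.remove(worst)
        else:
            break
    return forced + remaining


@dataclass
class DiagnosticsRecord:
    """Formal model checks for a linear fit.

    ``None`` p-values mean the test was not applicable (e.g. lack-of-fit
    without replicated design rows); the reason is recorded in ``notes``.
    """

    normality_p: float | None
    constant_variance_p: float | None
    linearity_p: float | None
    influential: list = field(default_factory=list)
    notes: dict = field(default_factory=dict)


def _lack_of_fit(res) -> tuple[float | None, str]:
    """Classical pure-error F-test; needs replicated design rows."""
    exog = np.asarray(res.model.exog)
    endog = np.asarray(res.model.endog)
    keys = [tuple(row) for row in exog]
    groups: dict = {}
    for i, k in enumerate(keys):
        groups.setdefault(k, []).append(i)
    m = len(groups)
    n = len(endog)
    p = exog.shape[1]
    df_pe = n - m
    df_lof = m - p
    if df_pe <= 0:
        return None, "no replicated design rows; pure-error lack-of-fit not applicable"
    if df_lof <= 0:
        return None, "too few distinct design rows for a lack-of-fit contrast"
    ss_pe = 0.0
    for idx in groups.values():
        yg = endog[list(idx)]
        ss_pe += float(np.sum((yg - yg.mean()) ** 2))
    sse = float(res.ssr)
    ss_lof = sse - ss_pe
    F = (ss_lof / df_lof) / (ss_pe / df_pe) if ss_pe > 0 else np.inf
    return float(stats.f.sf(F, df_lof, df_pe)), "pure-error F-test"


def run_diagnostics(
    res, leverage_factor: float = 2.0, studentized_cutoff: float = 3.0
) -> DiagnosticsRecord:
    """Formal assumption checks and influence screening for an OLS fit.

    Normality: Kolmogorov-Smirnov of standardized residuals against N(0,1)
    (estimated scale; treated as known, noted).  Constant variance: White's
    general test (LM p-value).  Linearity: pure-error lack-of-fit F where the
    design has replicated rows, else flagged not applicable.  Influential
    observations: leverage > ``leverage_factor * p / n`` or externally
    studentized residual beyond ``studentized_cutoff``.
    """
    notes: dict = {}
    resid = np.asarray(res.resid, dtype=float)
    z = (resid - resid.mean()) / resid.std(ddof=1)
    normality_p = float(stats.kstest(z, "norm").pvalue)
    notes["normality"] = "KS vs standard normal on standardized residuals (scale estimated)"

    try:
        white = het_white(resid, np.asarray(res.model.exog))
        constant_variance_p = float(white[1])
        notes["constant_variance"] = "White general test, LM p-value"
    except (ValueError, np.linalg.LinAlgError) as exc:
        constant_variance_p = None
        notes["constant_variance"] = f"not applicable: {exc}"

    linearity_p, lof_note = _lack_of_fit(res)
    notes["linearity"] = lof_note

    infl = OLSInfluence(res)
    lev = infl.hat_matrix_diag
    stud = infl.resid_studentized_external
    n = int(res.nobs)
    p = len(res.params)
    thr = leverage_factor * p / n
    mask = (lev > thr) | (np.abs(stud) > studentized_cutoff)
    labels = list(res.model.data.row_labels) if res.model.data.row_labels is not None else list(range(n))
    influential = [labels[i] for i in np.flatnonzero(mask)]
    notes["influence_rule"] = f"leverage > {leverage_factor}p/n or |studentized residual| > {studentized_cutoff}"
    return DiagnosticsRecord(
        normality_p=normality_p,
        constant_variance_p=constant_variance_p,
        linearity_p=linearity_p,
        influential=influential,
        notes=notes,
    )


@dataclass
class EffectEstimate:
    """An IQR-scaled exposure effect with its provenance.

    For linear models the estimate is in outcome units (g) per IQR increase;
    for logistic models it is the odds ratio per IQR increase.  The
    influential-observation refit is reported alongside the primary fit,
    with ``conclusions_changed`` true when the two disagree on significance
    at alpha = 0.05.
    """

    outcome: str
    exposure: str
    family: str
    estimate: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    iqr: float
    coef_per_unit: float
    covariates: list
    diagnostics: DiagnosticsRecord | None = None
    influential_subjects: list = field(default_factory=list)
    refit_estimate: float | None = None
    refit_ci: tuple | None = None
    refit_p: float | None = None
    conclusions_changed: bool | None = None

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("confidence interval must bracket the estimate")


def fit_linear_effect(
    data: pd.DataFrame,
    outcome: str,
    exposure: str,
    covariates,
    iqr: float,
    alpha: float = 0.05,
) -> EffectEstimate:
    """OLS of a continuous outcome on continuous exposure plus covariates.

    The exposure coefficient and its Wald CI are multiplied by ``iqr`` so the
    report reads as outcome change per IQR increase.  Diagnostics are run on
    the primary fit and the model is refitted without influential subjects;
    both estimates are reported.
    """
    covariates = list(covariates)
    df = _complete_cases(data, [outcome, exposure, *covariates])
    if len(df) < len(covariates) + 5:
        raise ValueError(f"too few complete cases ({len(df)}) for the requested model")
    X, _ = build_design(df, [exposure, *covariates])
    _check_constant(X)
    res = _fit(df[outcome], X, "linear")
    coef = float(res.params[exposure])
    ci = res.conf_int().loc[exposure]
    diag = run_diagnostics(res)

    if diag.influential:
        keep = df.index.difference(pd.Index(diag.influential))
        df2 = df.loc[keep]
        X2, _ = build_design(df2, [exposure, *covariates])
        res2 = _fit(df2[outcome], X2, "linear")
    else:
        res2 = res  # removing zero subjects reproduces the original fit exactly
    coef2 = float(res2.params[exposure])
    ci2 = res2.conf_int().loc[exposure]
    p2 = float(res2.pvalues[exposure])
    p1 = float(res.pvalues[exposure])

    return EffectEstimate(
        outcome=outcome,
        exposure=exposure,
        family="linear",
        estimate=coef * iqr,
        ci_low=float(ci[0]) * iqr,
        ci_high=float(ci[1]) * iqr,
        p=p1,
        n=len(df),
        iqr=iqr,
        coef_per_unit=coef,
        covariates=covariates,
        diagnostics=diag,
        influential_subjects=list(diag.influential),
        refit_estimate=coef2 * iqr,
        refit_ci=(float(ci2[0]) * iqr, float(ci2[1]) * iqr),
        refit_p=p2,
        conclusions_changed=bool((p1 < alpha) != (p2 < alpha)),
    )


def fit_logistic_effect(
    data: pd.DataFrame,
    outcome: str,
    exposure: str,
    covariates,
    iqr: float,
) -> EffectEstimate:
    """Logistic regression; reports the odds ratio per IQR increase (Wald CI)."""
    covariates = list(covariates)
    df = _complete_cases(data, [outcome, exposure, *covariates])
    y = df[outcome].astype(float)
    if y.nunique() < 2:
        raise ValueError("both outcome classes must be present")
    X, _ = build_design(df, [exposure, *covariates])
    _check_constant(X)
    res = _fit(y, X, "logistic")
    coef = float(res.params[exposure])
    ci = res.conf_int().loc[exposure]
    return EffectEstimate(
        outcome=outcome,
        exposure=exposure,
        family="logistic",
        estimate=float(np.exp(coef * iqr)),
        ci_low=float(np.exp(ci[0] * iqr)),
        ci_high=float(np.exp(ci[1] * iqr)),
        p=float(res.pvalues[exposure]),
        n=len(df),
        iqr=iqr,
        coef_per_unit=coef,
        covariates=covariates,
        diagnostics=None,
    )


@dataclass
class InteractionResult:
    term_a: str
    term_b: str
    p: float
    flagged: bool
    threshold: float
    stratified: dict | None = None


def test_interaction(
    data: pd.DataFrame,
    outcome: str,
    term_a: str,
    term_b: str,
    covariates=(),
    family: str = "linear",
    threshold: float = 0.20,
) -> InteractionResult:
    """Cross-product effect-modification test with stratified follow-up.

    The model contains both main effects, the covariates, and the
    ``term_a x term_b`` cross-product; the cross-product's Wald p is compared
    to the liberal ``threshold`` (default 0.20).  When flagged and ``term_b``
    is categorical with few levels, per-level fits of ``outcome ~ term_a +
    covariates`` are returned.
    """
    covariates = list(covariates)
    df = _complete_cases(data, [outcome, term_a, term_b, *covariates])
    X, groups = build_design(df, [term_a, term_b, *covariates])
    a_cols, b_cols = groups[term_a], groups[term_b]
    if len(a_cols) != 1:
        raise ValueError("term_a must be a single-column (numeric or binary) term")
    cross_cols = []
    for bc in b_cols:
        name = f"{a_cols[0]}:{bc}"
        X[name] = X[a_cols[0]] * X[bc]
        cross_cols.append(name)
    _check_constant(X)
    res = _fit(df[outcome], X, family)
    if len(cross_cols) == 1:
        p = float(res.pvalues[cross_cols[0]])
    else:
        exog_names = list(res.model.exog_names)
        R = np.zeros((len(cross_cols), len(exog_names)))
        for i, c in enumerate(cross_cols):
            R[i, exog_names.index(c)] = 1.0
        p = float(res.wald_test(R, scalar=True).pvalue)
    flagged = bool(p < threshold)

    stratified = None
    levels = df[term_b].unique()
    if flagged and len(levels) <= 3:
        stratified = {}
        for lev in sorted(levels, key=str):
            sub = df[df[term_b] == lev]
            Xs, _ = build_design(sub, [term_a, *covariates])
            try:
                _check_constant(Xs)
                r = _fit(sub[outcome], Xs, family)
            except (DegenerateDesignError, SeparationError) as exc:
                stratified[lev] = {"error": str(exc)}
                continue
            cis = r.conf_int().loc[term_a]
            stratified[lev] = {
                "coef": float(r.params[term_a]),
                "ci": (float(cis[0]), float(cis[1])),
                "p": float(r.pvalues[term_a]),
                "n": int(r.nobs),
            }
    return InteractionResult(
        term_a=term_a, term_b=term_b, p=p, flagged=flagged, threshold=threshold, stratified=stratified
    )
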