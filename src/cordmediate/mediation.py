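"""Baron-Kenny four-model mediation cascade.

Tests whether a gene's log2 expression in cord blood mediates the association
between dichotomized arsenic exposure (high vs median-or-low, from the
extreme-group classification) and birth weight in grams:

* **Model 1** BW ~ As + sex + GA + smoking + parity - the exposure must
  predict the outcome.
* **Model 2** expression ~ As + sex + GA - the exposure must predict the
  mediator (coefficient = log2 fold change of high-exposed vs the rest).
* **Model 3** BW ~ expression + sex + GA + smoking + parity - the mediator
  must predict the outcome.
* **Model 4** model 3 + As - the mediator must remain a significant predictor
  while controlling for exposure, and the exposure coefficient must be
  attenuated relative to model 1.

Effect modification by sex is probed in every model with a cross-product term
at the liberal p < 0.20 threshold; when the mediator x sex term is flagged in
models 3/4, sex-specific mediator effects (g per doubling of expression, since
expression is log2) are reported via linear contrasts.

Verdict: ``partial`` when all four requirements hold and the model-4 exposure
effect is still significant; ``full`` when all hold but the model-4 exposure
effect is no longer significant at alpha = 0.05 (a finite-sample reading of
"drops to zero"); ``none`` otherwise.  The per-requirement trace is kept so
failed cascades show exactly where they stopped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .association import DegenerateDesignError, _check_constant, build_design

__all__ = ["MediationError", "ModelFit", "MediationResult", "run_baron_kenny", "sensitivity_analysis"]

ALPHA = 0.05
INTERACTION_THRESHOLD = 0.20


class MediationError(ValueError):
    """Preconditions for the cascade are violated."""


@dataclass
class ModelFit:
    """One fitted regression of the cascade, reduced to its reportable parts."""

    name: str
    n: int
    terms: pd.DataFrame  # index term; columns beta, ci_low, ci_high, p
    interaction_term: str | None = None
    interaction_p: float | None = None
    interaction_included: bool = False
    by_sex: dict | None = None  # sex -> {beta, ci_low, ci_high, p} for the focal term

    def beta(self, term: str) -> float:
        return float(self.terms.loc[term, "beta"])

    def p(self, term: str) -> float:
        return float(self.terms.loc[term, "p"])


@dataclass
class MediationResult:
    gene: str
    models: dict
    beta_as_m1: float
    beta_as_m4: float
    attenuation: float
    requirements: dict
    verdict: str
    alpha: float = ALPHA
    notes: dict = field(default_factory=dict)

    def significant_flags(self) -> dict:
        """The significance conclusions compared by sensitivity analyses."""
        flags = {
            "m1_as": self.requirements["r1"]["met"],
            "m2_as": self.requirements["r2"]["met"],
            "m3_mediator": self.requirements["r3"]["met"],
            "m4_mediator": self.requirements["r4"]["mediator_significant"],
            "m4_as": self.models["model4"].p("high_as") < self.alpha,
        }
        return flags


def _ols(df: pd.DataFrame, outcome: str, terms) -> tuple:
    X, groups = build_design(df, list(terms))
    _check_constant(X)
    res = sm.OLS(df[outcome].astype(float), sm.add_constant(X, has_constant="add")).fit()
    return res, groups


def _terms_table(res) -> pd.DataFrame:
    ci = res.conf_int()
    return pd.DataFrame(
        {
            "beta": res.params,
            "ci_low": ci[0],
            "ci_high": ci[1],
            "p": res.pvalues,
        }
    )


def _contrast(res, weights: dict) -> dict:
    names = list(res.model.exog_names)
    L = np.zeros(len(names))
    for term, w in weights.items():
        L[names.index(term)] = w
    t = res.t_test(L)
    ci = t.conf_int()
    return {
        "beta": float(np.squeeze(t.effect)),
        "ci_low": float(ci[0, 0]),
        "ci_high": float(ci[0, 1]),
        "p": float(np.squeeze(t.pvalue)),
    }


def _fit_with_optional_interaction(
    df: pd.DataFrame,
    outcome: str,
    focal: str,
    base_terms: list,
    name: str,
    threshold: float = INTERACTION_THRESHOLD,
) -> ModelFit:
    """Fit outcome ~ focal + base terms, testing a focal x sex cross-product.

    The cross-product is included iff its p-value is below ``threshold``; in
    that case sex-specific focal effects are derived by linear contrasts
    (``boy`` is the 0/1 indicator column).
    """
    inter = f"{focal}:boy"
    df = df.copy()
    df[inter] = df[focal].astype(float) * df["boy"].astype(float)
    res_int, _ = _ols(df, outcome, [focal, *base_terms, inter])
    p_int = float(res_int.pvalues[inter])
    included = p_int < threshold
    if included:
        res = res_int
        by_sex = {
            "girl": _contrast(res, {focal: 1.0}),
            "boy": _contrast(res, {focal: 1.0, inter: 1.0}),
        }
    else:
        res, _ = _ols(df, outcome, [focal, *base_terms])
        by_sex = None
    return ModelFit(
        name=name,
        n=int(res.nobs),
        terms=_terms_table(res),
        interaction_term=inter,
        interaction_p=p_int,
        interaction_included=included,
        by_sex=by_sex,
    )


def _focal_significant(fit: ModelFit, focal: str, alpha: float) -> tuple[bool, dict]:
    """Significance of the focal term; any-stratum rule under interaction."""
    if fit.interaction_included and fit.by_sex:
        ps = {sex: v["p"] for sex, v in fit.by_sex.items()}
        return bool(min(ps.values()) < alpha), {"stratified_p": ps}
    return bool(fit.p(focal) < alpha), {"p": fit.p(focal)}


def _assemble(cohort: pd.DataFrame, expression: pd.Series, high_as: pd.Series) -> pd.DataFrame:
    df = pd.DataFrame(index=cohort.index)
    df["bw"] = cohort["birth_weight_g"].astype(float)
    df["high_as"] = high_as.reindex(cohort.index).astype(float)
    df["boy"] = (cohort["sex"] == "boy").astype(float)
    df["ga"] = cohort["ga_weeks"].astype(float)
    df["smoking"] = cohort["smoking"].astype(float)
    df["parity_0"] = (cohort["parity"] == 0).astype(float)
    df["parity_1"] = (cohort["parity"] == 1).astype(float)
    df["mediator"] = expression.reindex(cohort.index).astype(float)
    for extra in ("maternal_bmi", "complications"):
        if extra in cohort.columns:
            df[extra] = cohort[extra].astype(float)
    return df


def run_baron_kenny(
    cohort: pd.DataFrame,
    expression: pd.Series,
    high_as: pd.Series,
    gene: str = "gene",
    alpha: float = ALPHA,
    extra_covariates=(),
) -> MediationResult:
    """Run the four-model cascade for one gene.

    Parameters
    ----------
    cohort : DataFrame
        Needs ``birth_weight_g``, ``sex`` ('boy'/'girl'), ``ga_weeks``,
        ``smoking`` and ``parity`` (0/1/2 meaning 0, 1, 2+).
    expression : Series
        Log2 expression of the candidate mediator, indexed like the cohort.
    high_as : Series of bool
        Dichotomous exposure: high vs median-or-low (see
        :meth:`cordmediate.exposure.ExposureClassing.high_vs_rest`).
    extra_covariates : sequence of str
        Additional numeric cohort columns forced into every model (used by
        the sensitivity analyses).
    """
    high_as = high_as.reindex(cohort.index)
    if high_as.isna().any():
        raise MediationError("exposure grouping missing for some subjects")
    if int(high_as.sum()) == 0:
        raise MediationError("high-exposure group is empty")
    expr = expression.reindex(cohort.index)
    if expr.isna().all() or float(np.nanstd(expr.to_numpy(dtype=float))) == 0.0:
        raise MediationError("mediator expression is constant or absent")

    df = _assemble(cohort, expr, high_as)
    extra = list(extra_covariates)
    bw_cov = ["boy", "ga", "smoking", "parity_0", "parity_1", *extra]
    expr_cov = ["boy", "ga", *extra]

    df1 = df.dropna(subset=["bw", "high_as", *bw_cov])
    m1 = _fit_with_optional_interaction(df1, "bw", "high_as", bw_cov, "model1")

    df2 = df.dropna(subset=["mediator", "high_as", *expr_cov])
    m2 = _fit_with_optional_interaction(df2, "mediator", "high_as", expr_cov, "model2")

    df3 = df.dropna(subset=["bw", "mediator", *bw_cov])
    m3 = _fit_with_optional_interaction(df3, "bw", "mediator", bw_cov, "model3")

    df4 = df.dropna(subset=["bw", "mediator", "high_as", *bw_cov])
    m4 = _fit_with_optional_interaction(df4, "bw", "mediator", [*bw_cov, "high_as"], "model4")

    r1_met, r1_info = _focal_significant(m1, "high_as", alpha)
    r2_met, r2_info = _focal_significant(m2, "high_as", alpha)
    r3_met, r3_info = _focal_significant(m3, "mediator", alpha)
    med4_sig, r4_info = _focal_significant(m4, "mediator", alpha)

    beta1 = m1.beta("high_as")
    beta4 = m4.beta("high_as")
    attenuated = abs(beta4) < abs(beta1)
    r4_met = bool(med4_sig and attenuated)

    requirements = {
        "r1": {"met": r1_met, "description": "exposure predicts birth weight (model 1)", **r1_info},
        "r2": {"met": r2_met, "description": "exposure predicts mediator expression (model 2)", **r2_info},
        "r3": {"met": r3_met, "description": "mediator expression predicts birth weight (model 3)", **r3_info},
        "r4": {
            "met": r4_met,
            "description": "mediator remains predictive controlling for exposure, with attenuation",
            "mediator_significant": bool(med4_sig),
            "attenuated": bool(attenuated),
            **r4_info,
        },
    }
    if all(requirements[k]["met"] for k in ("r1", "r2", "r3", "r4")):
        verdict = "full" if m4.p("high_as") >= alpha else "partial"
    else:
        verdict = "none"

    return MediationResult(
        gene=gene,
        models={"model1": m1, "model2": m2, "model3": m3, "model4": m4},
        beta_as_m1=beta1,
        beta_as_m4=beta4,
        attenuation=beta1 - beta4,
        requirements=requirements,
        verdict=verdict,
        alpha=alpha,
        notes={"exposure_contrast": "high vs median-or-low", "mediator_scale": "log2 (effects per doubling)"},
    )


@dataclass
class SensitivityComparison:
    baseline_verdict: str
    options: dict  # option -> {verdict, flags, preserved}

    @property
    def all_preserved(self) -> bool:
        return all(v["preserved"] for v in self.options.values())


def sensitivity_analysis(
    cohort: pd.DataFrame,
    expression: pd.Series,
    high_as: pd.Series,
    gene: str = "gene",
    add_bmi: bool = False,
    adjust_complications: bool = False,
    exclude_complications: bool = False,
) -> SensitivityComparison:
    """Refit the cascade under robustness variants and compare conclusions.

    ``add_bmi`` forces maternal BMI into every model; ``adjust_complications``
    forces the pregnancy-complications flag in; ``exclude_complications``
    drops subjects reporting complications.  Each requested option refits all
    four models and records whether every significance conclusion (p < 0.05
    flag) of the baseline cascade is preserved.  With no options requested the
    comparison record reduces to the baseline.
    """
    baseline = run_baron_kenny(cohort, expression, high_as, gene=gene)
    base_flags = baseline.significant_flags()

    options: dict = {}

    def _compare(name: str, res: MediationResult) -> None:
        flags = res.significant_flags()
        options[name] = {
            "verdict": res.verdict,
            "flags": flags,
            "preserved": flags == base_flags,
        }

    if add_bmi:
        if "maternal_bmi" not in cohort.columns:
            raise KeyError("cohort lacks maternal_bmi")
        _compare("add_bmi", run_baron_kenny(cohort, expression, high_as, gene=gene, extra_covariates=["maternal_bmi"]))
    if adjust_complications:
        if "complications" not in cohort.columns:
            raise KeyError("cohort lacks complications")
        _compare(
            "adjust_complications",
            run_baron_kenny(cohort, expression, high_as, gene=gene, extra_covariates=["complications"]),
        )
    if exclude_complications:
        if "complications" not in cohort.columns:
            raise KeyError("cohort lacks complications")
        keep = cohort.index[cohort["complications"] == 0]
        sub = cohort.loc[keep]
        if int(high_as.reindex(keep).sum()) == 0 or len(sub) == 0:
            raise MediationError("excluding complications empties a group")
        _compare(
            "exclude_complications",
            run_baron_kenny(sub, expression.reindex(keep), high_as.reindex(keep), gene=gene),
        )

    return SensitivityComparison(baseline_verdict=baseline.verdict, options=options)
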