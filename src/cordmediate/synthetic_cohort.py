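"""Synthetic mother-newborn cohorts with matched expression and qPCR data.

The generator emulates the statistical structure a low-exposure cord-blood
biomonitoring study assumes, so that every downstream stage (exposure
classification, SGA derivation, regression models, quadrant screen, mediation
cascade, qPCR confirmation) has a ground-truth test bed:

* cord-blood arsenic is lognormal (geometric mean 0.56 ug/L, geometric SD
  3.25), censored below an LOD of 0.028 ug/L; maternal arsenic is correlated
  with cord arsenic on the ln scale (r = 0.82);
* birth weight follows a linear model in gestational age (+216 g/week), sex
  (+161 g for boys), maternal smoking (-111 g), parity (-184 g for 0 vs 2+,
  -30 g for 1 vs 2+) and arsenic (-47 g per theoretical IQR of the latent
  exposure), plus a girls-only mediator path and Gaussian residual;
* one planted mediator gene ("SFLT1", transcript NM_001159920) is shifted by
  +0.30 log2 units in the empirically classified high-arsenic group and
  lowers birth weight in girls by 182 g per doubling; all other genes are
  expression noise independent of exposure and outcome;
* sex-specific 10th-percentile reference curves are derived from the
  generator's own marginal birth-weight distribution by large-scale
  simulation, so ~10% of a fresh cohort is SGA by construction;
* Cq tables for the mediator transcripts and three reference genes track
  -1 x log2 expression plus loading and measurement noise, with loading
  cancelling under multi-reference normalization.

Distributional choices the emulated study design does not pin down (the
gestational-age table, smoking prevalence, parity mix, noise scales) are
explicit config fields with documented defaults; they are deliberate
modelling choices, not estimates of any real population.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .birth_outcomes import GrowthCurveTable
from .exposure import classify_exposure, impute_below_lod
from .transcriptome import FLAG_NAMES, ExpressionMatrix

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "generate_cohort",
    "generate_expression",
    "generate_reference_curves",
    "generate_qpcr",
    "write_cohort",
    "read_cohort",
]

MEDIATOR_GENE = "SFLT1"
MEDIATOR_TRANSCRIPT = "NM_001159920"
SECOND_TRANSCRIPT = "NM_001160030"
REFERENCE_GENES = ("GNB2L1", "RPLP0", "RPL13A")

#: completed gestational weeks 34..42 and their probabilities; peaked at 40
#: with median 40, consistent with a term-dominated singleton cohort.
GA_WEEKS = tuple(range(34, 43))
GA_PROBS = (0.010, 0.015, 0.025, 0.060, 0.130, 0.220, 0.280, 0.190, 0.070)

_Z75 = stats.norm.ppf(0.75)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study, with the emulated design as defaults."""

    n_subjects: int = 183
    # exposure model
    as_geomean: float = 0.56          # ug/L
    as_gsd: float = 3.25              # multiplicative geometric SD
    as_lod: float = 0.028             # ug/L
    maternal_cord_log_corr: float = 0.82
    # gestational age (completed weeks)
    ga_weeks: tuple = GA_WEEKS
    ga_probs: tuple = GA_PROBS
    # birth-weight linear model (grams); GA centred at 40 weeks
    bw_intercept: float = 3650.0
    beta_ga: float = 216.0            # g per week
    beta_sex_boys: float = 161.0      # g, boys vs girls
    beta_smoking: float = -111.0      # g, yes vs no
    beta_parity_0: float = -184.0     # g, 0 vs 2+
    beta_parity_1: float = -30.0      # g, 1 vs 2+
    beta_as_per_iqr: float = -47.0    # g per theoretical IQR of latent exposure
    residual_bw_sd: float = 400.0     # g
    # planted mediator
    mediator_log2fc_high_as: float = 0.30      # log2 units, high vs rest
    mediator_bw_effect_girls: float = -182.0   # g per doubling of expression
    mediator_bw_effect_boys: float = 0.0
    mediator_baseline_log2: float = 9.0
    # expression matrix
    n_null_genes: int = 369
    expression_noise_sd: float = 0.50          # log2 units, per subject
    probe_noise_sd: float = 0.10               # log2 units, per probe replicate
    replicate_probe_fraction: float = 0.30
    unreliable_fraction: float = 0.02          # P(feature carries a failing flag)
    # covariate distributions (documented guesses, not population claims)
    boy_prob: float = 0.5
    smoking_prevalence: float = 0.12
    parity_probs: tuple = (0.45, 0.38, 0.17)   # 0, 1, 2+
    complication_prevalence: float = 8.0 / 183.0
    n_missing_birthweight: int = 6
    n_missing_maternal_as: int = 6
    # qPCR
    qpcr_noise_sd: float = 0.15                # cycles
    qpcr_loading_sd: float = 0.30              # cycles, per-sample shift
    qpcr_second_transcript_noise: float = 0.25 # log2 units between variants
    # reference curves
    curve_sim_size: int = 20000
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        for name in ("residual_bw_sd", "expression_noise_sd", "probe_noise_sd", "qpcr_noise_sd", "qpcr_loading_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.as_gsd <= 1:
            raise ValueError("as_gsd must exceed 1 (multiplicative SD)")
        if self.as_geomean <= 0 or self.as_lod <= 0:
            raise ValueError("as_geomean and as_lod must be positive")
        if not 0 <= self.maternal_cord_log_corr <= 1:
            raise ValueError("maternal_cord_log_corr must be in [0, 1]")
        if len(self.ga_weeks) != len(self.ga_probs) or abs(sum(self.ga_probs) - 1) > 1e-9:
            raise ValueError("ga_probs must match ga_weeks and sum to 1")
        if min(self.ga_weeks) < 20 or max(self.ga_weeks) > 45:
            raise ValueError("gestational-age range must lie within 20-45 weeks")
        if not 0 <= self.replicate_probe_fraction <= 1 or not 0 <= self.unreliable_fraction <= 1:
            raise ValueError("fractions must lie in [0, 1]")
        if abs(sum(self.parity_probs) - 1) > 1e-9:
            raise ValueError("parity_probs must sum to 1")

    @property
    def as_log_sd(self) -> float:
        return float(np.log(self.as_gsd))

    @property
    def as_iqr_theoretical(self) -> float:
        """IQR of the latent lognormal exposure (ug/L): the scale on which
        ``beta_as_per_iqr`` is interpreted."""
        s = self.as_log_sd
        return float(self.as_geomean * (np.exp(_Z75 * s) - np.exp(-_Z75 * s)))

    def replace(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated cohort; round-trips through JSON."""

    mediator_gene: str
    mediator_transcript: str
    coefficients: dict
    latent_as: np.ndarray
    mediator_log2: np.ndarray
    high_as: np.ndarray
    linear_predictor: np.ndarray

    def to_json(self, path=None) -> str:
        payload = {
            "mediator_gene": self.mediator_gene,
            "mediator_transcript": self.mediator_transcript,
            "coefficients": self.coefficients,
            "latent_as": self.latent_as.tolist(),
            "mediator_log2": self.mediator_log2.tolist(),
            "high_as": self.high_as.astype(int).tolist(),
            "linear_predictor": self.linear_predictor.tolist(),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "SyntheticTruth":
        if isinstance(source, (str, Path)) and Path(str(source)).exists():
            payload = json.loads(Path(source).read_text())
        else:
            payload = json.loads(source)
        return cls(
            mediator_gene=payload["mediator_gene"],
            mediator_transcript=payload["mediator_transcript"],
            coefficients=payload["coefficients"],
            latent_as=np.asarray(payload["latent_as"], dtype=float),
            mediator_log2=np.asarray(payload["mediator_log2"], dtype=float),
            high_as=np.asarray(payload["high_as"], dtype=int).astype(bool),
            linear_predictor=np.asarray(payload["linear_predictor"], dtype=float),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, SyntheticTruth):
            return NotImplemented
        return (
            self.mediator_gene == other.mediator_gene
            and self.mediator_transcript == other.mediator_transcript
            and self.coefficients == other.coefficients
            and np.array_equal(self.latent_as, other.latent_as)
            and np.array_equal(self.mediator_log2, other.mediator_log2)
            and np.array_equal(self.high_as, other.high_as)
            and np.array_equal(self.linear_predictor, other.linear_predictor)
        )


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent, reproducible streams per generator stage
    return np.random.default_rng([stream, config.seed])


def _draw_covariates(rng, n: int, config: SimulationConfig) -> dict:
    return {
        "boy": rng.random(n) < config.boy_prob,
        "smoking": (rng.random(n) < config.smoking_prevalence).astype(int),
        "parity": rng.choice([0, 1, 2], size=n, p=config.parity_probs),
        "complications": (rng.random(n) < config.complication_prevalence).astype(int),
    }


def _bw_predictor(config, ga, boy, smoking, parity, latent_as, mediator_centered):
    return (
        config.bw_intercept
        + config.beta_ga * (np.asarray(ga, dtype=float) - 40.0)
        + config.beta_sex_boys * np.asarray(boy, dtype=float)
        + config.beta_smoking * np.asarray(smoking, dtype=float)
        + config.beta_parity_0 * (np.asarray(parity) == 0)
        + config.beta_parity_1 * (np.asarray(parity) == 1)
        + config.beta_as_per_iqr * (np.asarray(latent_as, dtype=float) / config.as_iqr_theoretical)
        + np.where(
            np.asarray(boy, dtype=bool),
            config.mediator_bw_effect_boys,
            config.mediator_bw_effect_girls,
        )
        * np.asarray(mediator_centered, dtype=float)
    )


def generate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw one mother-newborn cohort and its ground truth.

    Deterministic for a fixed seed.  The mediator's high-arsenic shift is
    keyed to the *empirical* extreme-group classification of the drawn
    exposures (the same classification the analysis will make), so planted
    group contrasts are exact in the zero-noise limit.
    """
    config.validate()
    n = config.n_subjects
    rng = _rng(config, 0)

    mu, sigma = np.log(config.as_geomean), config.as_log_sd
    ln_as = rng.normal(mu, sigma, size=n)
    latent_as = np.exp(ln_as)
    below_lod = latent_as < config.as_lod

    rho = config.maternal_cord_log_corr
    ln_mat = mu + rho * (ln_as - mu) + np.sqrt(max(0.0, 1 - rho**2)) * sigma * rng.normal(size=n)
    maternal_as = np.exp(ln_mat)

    ga = rng.choice(np.asarray(config.ga_weeks, dtype=int), size=n, p=config.ga_probs)
    cov = _draw_covariates(rng, n, config)
    maternal_age = np.clip(rng.normal(30.2, 4.4, size=n), 18, 45).round(1)
    maternal_height = np.clip(rng.normal(167.0, 6.3, size=n), 145, 195).round(1)
    maternal_bmi = np.clip(rng.normal(24.3, 3.9, size=n), 16, 45).round(1)
    education = rng.choice(["low", "mid", "high"], size=n, p=[0.15, 0.40, 0.45])

    # empirical extreme-group classification drives the planted mediator shift
    imputed = impute_below_lod(latent_as, config.as_lod, below_lod)
    if n >= 3 and np.std(np.log(imputed)) > 0:
        high_as = classify_exposure(imputed).labels.to_numpy() == "high"
    else:
        high_as = latent_as > config.as_geomean * config.as_gsd

    mediator = (
        config.mediator_baseline_log2
        + config.mediator_log2fc_high_as * high_as
        + (rng.normal(0.0, config.expression_noise_sd, size=n) if config.expression_noise_sd > 0 else 0.0)
    )
    mediator = np.asarray(mediator, dtype=float)

    lp = _bw_predictor(
        config, ga, cov["boy"], cov["smoking"], cov["parity"], latent_as,
        mediator - config.mediator_baseline_log2,
    )
    resid = rng.normal(0.0, config.residual_bw_sd, size=n) if config.residual_bw_sd > 0 else np.zeros(n)
    bw = lp + resid
    head = 34.4 + 0.47 * (ga - 40.0) + 0.4 * cov["boy"] + rng.normal(0.0, 1.2, size=n)

    cohort = pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:04d}" for i in range(n)],
            "sex": np.where(cov["boy"], "boy", "girl"),
            "ga_weeks": ga.astype(int),
            "birth_weight_g": bw,
            "head_circumference_cm": head.round(1),
            "as_cord_ugL": latent_as,
            "as_cord_below_lod": below_lod,
            "as_maternal_ugL": maternal_as,
            "smoking": cov["smoking"],
            "parity": cov["parity"].astype(int),
            "maternal_age_y": maternal_age,
            "maternal_height_cm": maternal_height,
            "maternal_bmi": maternal_bmi,
            "education": education,
            "complications": cov["complications"],
        }
    ).set_index("subject_id")

    if config.n_missing_maternal_as > 0:
        miss = rng.choice(n, size=min(config.n_missing_maternal_as, n), replace=False)
        cohort.iloc[miss, cohort.columns.get_loc("as_maternal_ugL")] = np.nan
    if config.n_missing_birthweight > 0:
        miss = rng.choice(n, size=min(config.n_missing_birthweight, n), replace=False)
        cohort.iloc[miss, cohort.columns.get_loc("birth_weight_g")] = np.nan

    truth = SyntheticTruth(
        mediator_gene=MEDIATOR_GENE,
        mediator_transcript=MEDIATOR_TRANSCRIPT,
        coefficients={
            "bw_intercept": config.bw_intercept,
            "beta_ga": config.beta_ga,
            "beta_sex_boys": config.beta_sex_boys,
            "beta_smoking": config.beta_smoking,
            "beta_parity_0": config.beta_parity_0,
            "beta_parity_1": config.beta_parity_1,
            "beta_as_per_iqr": config.beta_as_per_iqr,
            "mediator_log2fc_high_as": config.mediator_log2fc_high_as,
            "mediator_bw_effect_girls": config.mediator_bw_effect_girls,
            "mediator_bw_effect_boys": config.mediator_bw_effect_boys,
            "as_iqr_theoretical": config.as_iqr_theoretical,
        },
        latent_as=latent_as,
        mediator_log2=mediator,
        high_as=np.asarray(high_as, dtype=bool),
        linear_predictor=lp,
    )
    return cohort, truth


# panel layout mirroring the emulated array's targeted gene panels:
# unique-gene weights for null-gene allocation (mediator joins the growth panel)
_PANELS = ("embryonal_growth", "dna_methylation", "oxidative_stress", "as_related")
_PANEL_WEIGHTS = (159, 49, 152, 9)


def _allocate_panels(n_genes: int) -> list:
    total = sum(_PANEL_WEIGHTS)
    raw = [n_genes * w / total for w in _PANEL_WEIGHTS]
    counts = [int(np.floor(r)) for r in raw]
    order = np.argsort([c - r for c, r in zip(counts, raw)])
    for i in range(n_genes - sum(counts)):
        counts[order[i % 4]] += 1
    panels = []
    for p, c in zip(_PANELS, counts):
        panels.extend([p] * c)
    return panels


def generate_expression(
    cohort: pd.DataFrame, truth: SyntheticTruth, config: SimulationConfig
) -> ExpressionMatrix:
    """Log2 expression matrix with the planted mediator and null genes.

    The mediator transcript is spotted once (its probe carries the exact
    planted per-subject values); null genes get a uniform baseline plus
    subject-level noise, a configurable fraction of genes a second replicate
    probe (with probe-level technical noise), and a small fraction of probes
    one failing reliability flag in one sample.  The mediator probe is always
    reliable, matching a candidate that survives quality control.
    """
    config.validate()
    rng = _rng(config, 1)
    n = len(cohort)
    samples = cohort.index

    n_null = config.n_null_genes
    genes = [f"GENE{i + 1:04d}" for i in range(n_null)]
    if MEDIATOR_GENE in genes:
        raise ValueError("mediator gene name collides with a null gene name")
    panels = _allocate_panels(n_null)

    baselines = rng.uniform(6.0, 12.0, size=n_null)
    noise = (
        rng.normal(0.0, config.expression_noise_sd, size=(n_null, n))
        if config.expression_noise_sd > 0
        else np.zeros((n_null, n))
    )
    gene_values = baselines[:, None] + noise

    duplicated = rng.random(n_null) < config.replicate_probe_fraction

    rows, probe_ids, ann_rows = [], [], []
    probe_no = 0

    def _add_probe(values, gene, transcript, panel):
        nonlocal probe_no
        probe_no += 1
        pid = f"A_23_P{probe_no:06d}"
        probe_ids.append(pid)
        rows.append(values)
        ann_rows.append({"gene_symbol": gene, "transcript": transcript, "panels": panel})
        return pid

    mediator_pid = _add_probe(
        truth.mediator_log2, MEDIATOR_GENE, MEDIATOR_TRANSCRIPT, "embryonal_growth"
    )
    for i, gene in enumerate(genes):
        transcript = f"NM_{900000 + i:06d}"
        reps = 2 if duplicated[i] else 1
        for _ in range(reps):
            pnoise = (
                rng.normal(0.0, config.probe_noise_sd, size=n)
                if config.probe_noise_sd > 0
                else 0.0
            )
            _add_probe(gene_values[i] + pnoise, gene, transcript, panels[i])

    values = pd.DataFrame(np.vstack(rows), index=probe_ids, columns=samples)
    annotation = pd.DataFrame(ann_rows, index=probe_ids)
    flags = {
        name: pd.DataFrame(True, index=probe_ids, columns=samples) for name in FLAG_NAMES
    }
    fail = rng.random(len(probe_ids)) < config.unreliable_fraction
    fail_flag = rng.integers(0, len(FLAG_NAMES), size=len(probe_ids))
    fail_sample = rng.integers(0, n, size=len(probe_ids))
    for i, pid in enumerate(probe_ids):
        if fail[i] and pid != mediator_pid:
            flags[FLAG_NAMES[fail_flag[i]]].iloc[i, fail_sample[i]] = False

    return ExpressionMatrix(values=values, flags=flags, annotation=annotation)


def generate_reference_curves(config: SimulationConfig) -> GrowthCurveTable:
    """Self-derived sex-specific P10 birth-weight curves.

    For every (sex, completed week) cell the 10th percentile of the
    generator's own marginal birth-weight distribution is estimated from
    ``curve_sim_size`` simulated subjects (marginalising over smoking,
    parity, exposure and the mediator path; the mediator's high-exposure
    shift uses the theoretical threshold geomean x GSD here).  Curves are
    forced monotone non-decreasing in week by a running maximum.
    """
    config.validate()
    rng = _rng(config, 2)
    m = config.curve_sim_size
    records = []
    for boy in (True, False):
        p10s = []
        for week in config.ga_weeks:
            cov = _draw_covariates(rng, m, config)
            latent = np.exp(rng.normal(np.log(config.as_geomean), config.as_log_sd, size=m))
            high = latent > config.as_geomean * config.as_gsd
            mediator = config.mediator_log2fc_high_as * high + (
                rng.normal(0.0, config.expression_noise_sd, size=m)
                if config.expression_noise_sd > 0
                else 0.0
            )
            bw = _bw_predictor(
                config, np.full(m, week), np.full(m, boy), cov["smoking"], cov["parity"],
                latent, mediator,
            )
            if config.residual_bw_sd > 0:
                bw = bw + rng.normal(0.0, config.residual_bw_sd, size=m)
            p10s.append(float(np.quantile(bw, 0.10)))
        p10s = np.maximum.accumulate(p10s)
        sex = "boy" if boy else "girl"
        records.extend(
            {"sex": sex, "ga_weeks": int(w), "p10_g": float(p)}
            for w, p in zip(config.ga_weeks, p10s)
        )
    return GrowthCurveTable(pd.DataFrame.from_records(records))


def generate_qpcr(
    cohort: pd.DataFrame,
    truth: SyntheticTruth,
    n_subset: int,
    config: SimulationConfig,
    mode: str = "extremes",
) -> pd.DataFrame:
    """Cq table for a sample subset: mediator transcripts + reference genes.

    ``mode='extremes'`` picks the highest- and lowest-exposure halves of the
    subset (the confirmation design); ``mode='random'`` samples uniformly.
    Cq of a target tracks -1 x its log2 expression plus a per-sample loading
    shift (cancelled by multi-reference normalization) and measurement noise;
    reference genes are flat in expression.  A second, correlated mediator
    transcript is emitted so transcript-variant concordance can be assessed.
    """
    config.validate()
    if n_subset > len(cohort):
        raise ValueError("subset larger than cohort")
    rng = _rng(config, 3)
    if n_subset == 0:
        return pd.DataFrame(columns=["sample_id", "target", "cq", "efficiency"])

    if mode == "extremes":
        order = cohort["as_cord_ugL"].sort_values()
        n_low = n_subset // 2
        n_high = n_subset - n_low
        subset = order.index[:n_low].append(order.index[-n_high:])
    elif mode == "random":
        subset = pd.Index(rng.choice(cohort.index.to_numpy(), size=n_subset, replace=False))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    pos = cohort.index.get_indexer(subset)
    m1 = truth.mediator_log2[pos]
    m2 = m1 + (
        rng.normal(0.0, config.qpcr_second_transcript_noise, size=len(subset))
        if config.qpcr_second_transcript_noise > 0
        else 0.0
    )
    loading = (
        rng.normal(0.0, config.qpcr_loading_sd, size=len(subset))
        if config.qpcr_loading_sd > 0
        else np.zeros(len(subset))
    )

    base_cq = {MEDIATOR_TRANSCRIPT: 26.0, SECOND_TRANSCRIPT: 27.0, "GNB2L1": 20.0, "RPLP0": 19.0, "RPL13A": 21.0}
    expr = {
        MEDIATOR_TRANSCRIPT: m1 - config.mediator_baseline_log2,
        SECOND_TRANSCRIPT: m2 - config.mediator_baseline_log2,
        "GNB2L1": np.zeros(len(subset)),
        "RPLP0": np.zeros(len(subset)),
        "RPL13A": np.zeros(len(subset)),
    }
    records = []
    for target, base in base_cq.items():
        noise = (
            rng.normal(0.0, config.qpcr_noise_sd, size=len(subset))
            if config.qpcr_noise_sd > 0
            else np.zeros(len(subset))
        )
        cq = base - expr[target] + loading + noise
        records.extend(
            {"sample_id": s, "target": target, "cq": float(c), "efficiency": 2.0}
            for s, c in zip(subset, cq)
        )
    return pd.DataFrame.from_records(records)


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path)


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="subject_id")
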