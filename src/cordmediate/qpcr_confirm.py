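"""qPCR confirmation of array-based expression.

Cq (quantification-cycle) data for target transcripts and a panel of
reference genes are converted to relative log2 expression with the
multi-reference normalization popularised by qBase: efficiency-corrected
relative quantities ``E**(Cq_ref_sample - Cq)`` are divided by the geometric
mean of the reference-gene quantities of the same sample, cancelling loading
differences, and expressed as log2 fold change versus a designated reference
sample.

Reference-gene stability is assessed with the geNorm M statistic: for gene j,
M_j is the mean over the other reference genes k of the standard deviation
across samples of the pairwise log2 ratio of j and k.  Perfectly parallel Cq
profiles give M = 0; lower M means more stable.  The iterative worst-gene
exclusion ranking is provided; the classical pairwise-variation V < 0.15
cutoff is advisory and not enforced.

Platform concordance pairs array and qPCR log2 fold changes on a matched
sample subset (Pearson), and re-runs the high-vs-low exposure Welch contrast
on each platform for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .transcriptome import WelchResult, welch_t

__all__ = [
    "CqSchemaError",
    "genorm_stability",
    "genorm_ranking",
    "relative_quantify",
    "platform_concordance",
    "ConcordanceResult",
]

CQ_COLUMNS = ("sample_id", "target", "cq", "efficiency")


class CqSchemaError(ValueError):
    """Cq table does not match the expected layout."""


def _cq_wide(cq: pd.DataFrame, targets) -> tuple[pd.DataFrame, pd.Series]:
    for col in CQ_COLUMNS:
        if col not in cq.columns:
            raise CqSchemaError(f"Cq table missing column {col!r}")
    sub = cq[cq["target"].isin(targets)]
    eff = sub.groupby("target")["efficiency"].first()
    if (sub.groupby("target")["efficiency"].nunique() > 1).any():
        raise CqSchemaError("per-target efficiency must be constant")
    wide = sub.pivot(index="sample_id", columns="target", values="cq")
    return wide, eff


def genorm_stability(cq: pd.DataFrame, reference_genes) -> pd.Series:
    """geNorm expression-stability measure M for each reference gene.

    Uses efficiency-corrected relative quantities on the log2 scale
    (``-Cq * log2(E)``); sample-wide Cq shifts cancel in the pairwise ratios,
    so loading differences do not affect M.  Standard deviations use the n-1
    denominator.
    """
    reference_genes = list(reference_genes)
    if len(reference_genes) < 2:
        raise ValueError("geNorm needs at least 2 reference genes")
    wide, eff = _cq_wide(cq, reference_genes)
    missing = set(reference_genes) - set(wide.columns)
    if missing:
        raise CqSchemaError(f"reference genes absent from Cq table: {sorted(missing)}")
    if wide[reference_genes].isna().any().any():
        raise CqSchemaError("every sample must have all reference genes measured")
    if len(wide) < 3:
        raise ValueError("geNorm needs at least 3 samples")
    log_q = {g: -wide[g].to_numpy(dtype=float) * np.log2(eff[g]) for g in reference_genes}
    M = {}
    for j in reference_genes:
        sds = [
            float(np.std(log_q[j] - log_q[k], ddof=1))
            for k in reference_genes
            if k != j
        ]
        M[j] = float(np.mean(sds))
    return pd.Series(M, name="genorm_M")


def genorm_ranking(cq: pd.DataFrame, reference_genes) -> list:
    """Iterative geNorm exclusion order, least stable dropped first.

    Returns gene names from least to most stable; the final two (which cannot
    be distinguished by M) are appended in ascending-M order.
    """
    remaining = list(reference_genes)
    dropped = []
    while len(remaining) > 2:
        M = genorm_stability(cq, remaining)
        worst = M.sort_values(ascending=False).index[0]
        dropped.append(worst)
        remaining.remove(worst)
    M = genorm_stability(cq, remaining)
    dropped.extend(M.sort_values(ascending=False).index.tolist())
    return dropped


def relative_quantify(
    cq: pd.DataFrame, reference_genes, reference_sample=None
) -> pd.DataFrame:
    """Multi-reference-normalized log2 fold changes versus a reference sample.

    For every target, the efficiency-corrected quantity
    ``E**(Cq(reference sample) - Cq(sample))`` is divided by the geometric
    mean of the reference-gene quantities of that sample and log2-ed.  The
    reference sample's value is exactly 0 for every target.  ``reference
    sample`` defaults to the lexicographically first sample id.
    """
    reference_genes = list(reference_genes)
    wide, eff = _cq_wide(cq, cq["target"].unique())
    missing_refs = set(reference_genes) - set(wide.columns)
    if missing_refs:
        raise CqSchemaError(f"reference genes absent from Cq table: {sorted(missing_refs)}")
    if wide[reference_genes].isna().any().any():
        bad = wide.index[wide[reference_genes].isna().any(axis=1)]
        raise CqSchemaError(f"missing reference gene Cq for samples: {list(bad[:5])}")
    if reference_sample is None:
        reference_sample = sorted(wide.index)[0]
    if reference_sample not in wide.index:
        raise KeyError(f"reference sample {reference_sample!r} not in Cq table")

    log2q = pd.DataFrame(index=wide.index)
    for tgt in wide.columns:
        log2q[tgt] = (wide.loc[reference_sample, tgt] - wide[tgt]) * np.log2(eff[tgt])
    norm = log2q[reference_genes].mean(axis=1)  # log2 of the geometric mean quantity
    out = log2q.sub(norm, axis=0)
    out.columns.name = None
    return out


@dataclass
class ConcordanceResult:
    r: float
    p: float
    n: int
    array_contrast: WelchResult
    qpcr_contrast: WelchResult


def platform_concordance(
    array_fc: pd.Series, qpcr_fc: pd.Series, groups: pd.Series
) -> ConcordanceResult:
    """Pearson agreement of paired array/qPCR log2 fold changes.

    ``groups`` labels each sample (e.g. 'high'/'low' arsenic); the
    high-vs-low Welch contrast is evaluated on each platform so the two
    readouts of differential expression can be compared directly.
    """
    common = array_fc.dropna().index.intersection(qpcr_fc.dropna().index)
    if len(common) < 3:
        raise ValueError("need at least 3 matched samples")
    a = array_fc.reindex(common).to_numpy(dtype=float)
    q = qpcr_fc.reindex(common).to_numpy(dtype=float)
    res = stats.pearsonr(a, q)
    g = groups.reindex(common)
    hi, lo = common[g == "high"], common[g == "low"]
    if len(hi) < 2 or len(lo) < 2:
        raise ValueError("need at least 2 samples per exposure group on the matched subset")
    return ConcordanceResult(
        r=float(res.statistic),
        p=float(res.pvalue),
        n=int(len(common)),
        array_contrast=welch_t(array_fc.reindex(hi), array_fc.reindex(lo)),
        qpcr_contrast=welch_t(qpcr_fc.reindex(hi), qpcr_fc.reindex(lo)),
    )
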