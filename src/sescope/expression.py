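"""Subtype differential expression.

Expression is analysed on the log2 scale, genes x samples, with each
sample labelled TNBC or nonTNBC. The per-gene test is a two-sample t
statistic with empirical-Bayes variance moderation: gene variances are
shrunk toward the grand mean variance with a prior weight expressed in
pseudo-observations, and the t reference distribution gains the same
degrees of freedom. Prior weight 0 recovers the ordinary pooled-variance
two-sample t exactly. A gene is called upregulated when its log2 fold
change exceeds 0.5 and its Benjamini-Hochberg adjusted p falls below 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

TNBC = "TNBC"
NON_TNBC = "nonTNBC"


@dataclass
class ExpressionMatrix:
    """log2 expression values with sample group labels."""

    values: pd.DataFrame                 # genes x samples
    group_labels: pd.Series              # sample -> {TNBC, nonTNBC}

    def __post_init__(self) -> None:
        self.group_labels = self.group_labels.reindex(self.values.columns)
        if self.group_labels.isna().any():
            missing = list(self.group_labels.index[self.group_labels.isna()])
            raise ValueError(f"samples without group label: {missing}")
        bad = set(self.group_labels.unique()) - {TNBC, NON_TNBC}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        counts = self.group_labels.value_counts()
        for g in (TNBC, NON_TNBC):
            if counts.get(g, 0) < 2:
                raise ValueError(f"group {g} needs at least 2 samples")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    def zscores(self) -> pd.DataFrame:
        """Per-gene z-scores across all samples (mean 0, sd 1)."""
        v = self.values
        sd = v.std(axis=1, ddof=1)
        return v.sub(v.mean(axis=1), axis=0).div(sd.replace(0, np.nan), axis=0)


@dataclass
class DEResult:
    gene_id: str
    log2fc: float            # mean(TNBC) - mean(nonTNBC)
    statistic: float
    p_value: float
    adj_p: float
    upregulated: bool
    unevaluable: bool = False


def upregulated_fraction(zscores: Sequence[float], threshold: float = 1.5) -> float:
    """Percentage of samples with z-score strictly above the threshold."""
    z = np.asarray(zscores, float)
    if z.size == 0:
        raise ValueError("empty z-score vector")
    if not np.isfinite(z).all():
        raise ValueError("z-scores must be finite")
    return 100.0 * float(np.sum(z > threshold)) / z.size


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adj_p[(i)] = min_{j >= i} ( m * p_(j) / j ), capped at 1, returned in
    the original order.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def differential_expression(
    matrix: ExpressionMatrix,
    prior_weight: float = 4.0,
    lfc_threshold: float = 0.5,
    alpha: float = 0.05,
) -> list[DEResult]:
    """Moderated two-sample test of TNBC vs nonTNBC per gene.

    Parameters
    ----------
    prior_weight
        Pseudo-observations shrinking each gene's pooled variance toward
        the grand mean variance; 0 gives the ordinary two-sample t.
    lfc_threshold, alpha
        The upregulation call: log2fc > lfc_threshold and BH-adjusted
        p < alpha.
    """
    if prior_weight < 0:
        raise ValueError("prior_weight must be non-negative")
    labels = matrix.group_labels
    a = matrix.values.loc[:, labels[labels == TNBC].index].to_numpy(float)
    b = matrix.values.loc[:, labels[labels == NON_TNBC].index].to_numpy(float)
    n1, n2 = a.shape[1], b.shape[1]
    df = n1 + n2 - 2

    mean1, mean2 = a.mean(axis=1), b.mean(axis=1)
    lfc = mean1 - mean2
    ss = ((a - mean1[:, None]) ** 2).sum(axis=1) + ((b - mean2[:, None]) ** 2).sum(axis=1)
    s2 = ss / df
    unevaluable = s2 == 0

    usable = ~unevaluable
    s2_prior = float(s2[usable].mean()) if usable.any() else 0.0
    if prior_weight > 0:
        s2_mod = (prior_weight * s2_prior + df * s2) / (prior_weight + df)
        df_mod = df + prior_weight
    else:
        s2_mod = s2
        df_mod = df

    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(np.abs(t), df_mod)
    t = np.where(unevaluable, np.nan, t)
    p = np.where(unevaluable, 1.0, p)
    adj = bh_adjust(p)
    up = (lfc > lfc_threshold) & (adj < alpha) & ~unevaluable

    return [
        DEResult(
            gene_id=g,
            log2fc=float(lfc[i]),
            statistic=float(t[i]),
            p_value=float(p[i]),
            adj_p=float(adj[i]),
            upregulated=bool(up[i]),
            unevaluable=bool(unevaluable[i]),
        )
        for i, g in enumerate(matrix.gene_ids)
    ]


def de_table(results: Sequence[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "log2fc": [r.log2fc for r in results],
            "statistic": [r.statistic for r in results],
            "p_value": [r.p_value for r in results],
            "adj_p": [r.adj_p for r in results],
            "upregulated": [r.upregulated for r in results],
        }
    ).set_index("gene_id")
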