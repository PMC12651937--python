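"""Two-group differential expression with empirical-Bayes variance moderation.

Per gene g a two-group linear model gives the log2 fold change and a pooled
residual variance s2_g on df_g = n - 2 degrees of freedom.  The gene-wise
variances are assumed exchangeable around a scaled inverse chi-square prior
with d0 degrees of freedom and scale s0^2; matching the first two moments of
log s2_g to the implied scaled-F distribution (digamma/trigamma inversion)
estimates (d0, s0^2), and the posterior variance

    s2_post = (d0 s0^2 + df_g s2_g) / (d0 + df_g)

yields a moderated t statistic on d0 + df_g degrees of freedom.  P-values
are adjusted by Benjamini-Hochberg.

A minimal per-batch location centering stands in for batch correction: per
gene, each batch's mean is shifted to the grand mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "batch_center",
    "fit_group_contrast",
    "eb_moderate",
    "moderated_t_and_bh",
    "ModerationFit",
]


@dataclass(frozen=True)
class ModerationFit:
    d0: float  # prior degrees of freedom (inf when variances look constant)
    s0_sq: float
    s2_post: np.ndarray
    converged: bool = True


def batch_center(
    matrix: pd.DataFrame,
    batch_labels: pd.Series,
    group_labels: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene location adjustment: shift each batch mean to the grand mean.

    Refuses when batch is perfectly confounded with group (every batch pure
    and more than one batch), since location effects are then inestimable.
    """
    if not set(matrix.columns) <= set(batch_labels.index):
        raise ValueError("every sample needs a batch label")
    batches = batch_labels.loc[matrix.columns]
    if group_labels is not None:
        groups = group_labels.loc[matrix.columns]
        purity = groups.groupby(batches, observed=True).nunique()
        if batches.nunique() > 1 and (purity == 1).all():
            raise ValueError(
                "batch is perfectly confounded with group; centering is inestimable"
            )
    x = matrix.to_numpy(float)
    grand = x.mean(axis=1, keepdims=True)
    out = x.copy()
    for b in batches.unique():
        mask = (batches == b).to_numpy()
        out[:, mask] += grand - x[:, mask].mean(axis=1, keepdims=True)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def fit_group_contrast(
    matrix: pd.DataFrame, labels: pd.Series, case: str = "case"
) -> pd.DataFrame:
    """Per-gene two-group contrast on a log2 matrix.

    Returns a DataFrame (gene, log2fc, s2_g, df_g) with
    log2fc = mean(case) - mean(control) and the pooled residual variance on
    n - 2 df.
    """
    groups = labels.loc[matrix.columns]
    levels = groups.unique()
    if len(levels) != 2:
        raise ValueError("exactly two groups required")
    is_case = (groups == case).to_numpy()
    n1, n2 = int(is_case.sum()), int((~is_case).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")
    x = matrix.to_numpy(float)
    xc, xn = x[:, is_case], x[:, ~is_case]
    log2fc = xc.mean(axis=1) - xn.mean(axis=1)
    ss = ((xc - xc.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (xn - xn.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    df_g = n1 + n2 - 2
    return pd.DataFrame(
        {
            "gene": matrix.index,
            "log2fc": log2fc,
            "s2_g": ss / df_g,
            "df_g": df_g,
            "n_case": n1,
            "n_ctrl": n2,
        }
    ).set_index("gene")


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone decreasing)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(100):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < 1e-8 * y:
            return float(y)
    return float(y)


def eb_moderate(s2, df) -> ModerationFit:
    """Estimate the variance prior (d0, s0^2) and posterior variances.

    Moment matching on z_g = log s2_g: under the scaled-F model
    E[z] = log s0^2 + digamma(d0/2) - log(d0/2) + digamma(df/2) - log(df/2)
    and Var[z] = trigamma(df/2) + trigamma(d0/2); the trigamma equation is
    inverted by Newton iteration.  When the observed log-variance spread is
    no larger than the sampling component, d0 = inf and all posterior
    variances collapse to s0^2.
    """
    s2 = np.asarray(s2, dtype=float)
    if s2.size < 10:
        raise ValueError("eb_moderate needs at least 10 genes")
    df = float(df)
    ok = s2 > 0
    if not ok.all():
        raise ValueError("all residual variances must be positive")
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) * (s2.size - 1) / s2.size
    excess = e_var - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        warnings.warn("eb_moderate: no excess variance dispersion; d0 = inf")
        # d0 = inf limit: every s2_g is unbiased for s0^2, so use their mean
        s0_sq = float(s2.mean())
        return ModerationFit(np.inf, s0_sq, np.full(s2.shape, s0_sq), False)
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = float(
        np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    )
    s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
    return ModerationFit(float(d0), s0_sq, s2_post)


def moderated_t_and_bh(
    contrasts: pd.DataFrame, moderation: ModerationFit
) -> pd.DataFrame:
    """Moderated t statistics, two-sided p-values, and BH adjustment.

    ``contrasts`` comes from :func:`fit_group_contrast`.  Genes with zero
    posterior variance and zero difference get p = 1 with a flag.
    """
    lfc = contrasts["log2fc"].to_numpy(float)
    df_g = contrasts["df_g"].to_numpy(float)
    n1 = contrasts["n_case"].to_numpy(float)
    n2 = contrasts["n_ctrl"].to_numpy(float)
    s2_post = np.asarray(moderation.s2_post, dtype=float)

    scale = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    degenerate = scale == 0.0
    t_mod = np.zeros_like(lfc)
    np.divide(lfc, scale, out=t_mod, where=~degenerate)
    df_total = moderation.d0 + df_g
    if np.isinf(moderation.d0):
        pval = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        pval = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    pval = np.where(degenerate & (lfc == 0.0), 1.0, pval)
    pval = np.where(degenerate & (lfc != 0.0), 0.0, pval)
    pval = np.clip(pval, 5e-324, 1.0)
    adj = multipletests(pval, method="fdr_bh")[1]
    out = contrasts.copy()
    out["s2_post"] = s2_post
    out["t_mod"] = t_mod
    out["df_total"] = df_total
    out["pval"] = pval
    out["adj_p"] = adj
    out["degenerate"] = degenerate
    return out
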