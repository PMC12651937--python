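"""Summary-data-based MR (SMR), the HEIDI heterogeneity filter, and gene tiers.

The SMR statistic asks whether a molecular trait (expression, protein, or
methylation level) and a complex trait share a causal variant.  At the top
QTL SNP the causal effect of the molecular trait on the outcome is the
ratio ``b_smr = b_gwas / b_qtl`` and its test statistic is the harmonic
combination

    T_smr = z_g^2 z_q^2 / (z_g^2 + z_q^2)  ~  chi-square(1)

which is bounded above by the weaker of the two z-scores squared.

HEIDI (heterogeneity in dependent instruments) distinguishes a single shared
causal variant from two distinct variants in LD: if the locus is driven by
one variant, the SMR ratio estimated at every nearby SNP is the same up to
sampling noise; under linkage the ratios disagree.  The test statistic sums
squared standardized deviations of per-SNP ratios from the top-SNP ratio and
its null distribution (correlated chi-squares) is evaluated by seeded Monte
Carlo sampling of the fitted multivariate normal.

Genes passing the HEIDI filter (p >= 0.05 from at least three SNPs) are
stratified into three evidence tiers from the breadth of modality support,
directional concordance, and Bonferroni-corrected significance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SMRResult",
    "HeidiResult",
    "smr_test",
    "heidi_test",
    "assign_significance_tier",
    "tier_genes",
]


@dataclass(frozen=True)
class SMRResult:
    b_smr: float
    se_smr: float
    p_smr: float
    t_smr: float


@dataclass(frozen=True)
class HeidiResult:
    p_heidi: float | None
    n_snp_used: int
    status: str  # "ok" or "filtered_too_few_snps"


def smr_test(
    b_gwas: float, se_gwas: float, b_qtl: float, se_qtl: float
) -> SMRResult:
    """SMR effect and test at the top QTL SNP."""
    if se_gwas <= 0 or se_qtl <= 0:
        raise ValueError("standard errors must be positive")
    if b_qtl == 0:
        raise ValueError("smr_test undefined for b_qtl = 0")
    z_g = b_gwas / se_gwas
    z_q = b_qtl / se_qtl
    b_smr = b_gwas / b_qtl
    t = (z_g**2 * z_q**2) / (z_g**2 + z_q**2)
    p = float(stats.chi2.sf(t, 1))
    se = abs(b_smr) / np.sqrt(t) if t > 0 else np.inf
    return SMRResult(float(b_smr), float(se), max(p, 5e-324), float(t))


def heidi_test(
    locus: pd.DataFrame,
    ld: pd.DataFrame,
    top_snp: str,
    r2_range: tuple[float, float] = (0.05, 0.9),
    min_z2_qtl: float = 10.0,
    max_snps: int = 20,
    n_draws: int = 20_000,
    seed: int = 42,
) -> HeidiResult:
    """HEIDI test for heterogeneity of SMR ratios across a locus.

    ``locus`` needs columns SNP, b_gwas, se_gwas, b_qtl, se_qtl; ``ld`` is
    the SNP x SNP correlation (r, not r^2) matrix.  SNPs are eligible when
    their r^2 to the top SNP lies strictly inside ``r2_range`` and their QTL
    z^2 clears ``min_z2_qtl``; the strongest (by QTL z^2) are kept up to
    ``max_snps``.  Fewer than three eligible SNPs returns a filtered status
    with no p-value.
    """
    loc = locus.set_index("SNP")
    if top_snp not in loc.index:
        raise ValueError(f"top SNP {top_snp!r} not in locus table")
    r_top = ld.loc[:, top_snp]
    z_q_all = loc["b_qtl"] / loc["se_qtl"]

    lo, hi = r2_range
    eligible = [
        s
        for s in loc.index
        if s != top_snp
        and lo < float(r_top.loc[s]) ** 2 < hi
        and float(z_q_all.loc[s]) ** 2 >= min_z2_qtl
    ]
    eligible.sort(key=lambda s: -float(z_q_all.loc[s]) ** 2)
    eligible = eligible[:max_snps]
    if len(eligible) < 3:
        return HeidiResult(None, len(eligible), "filtered_too_few_snps")

    snps = eligible + [top_snp]
    g = loc.loc[snps, "b_gwas"].to_numpy(float)
    sg = loc.loc[snps, "se_gwas"].to_numpy(float)
    q = loc.loc[snps, "b_qtl"].to_numpy(float)
    sq = loc.loc[snps, "se_qtl"].to_numpy(float)
    r = ld.loc[snps, snps].to_numpy(float)
    m = len(eligible)

    # d_i = g_i/q_i - g_top/q_top; delta-method covariance from the LD-implied
    # covariances of the GWAS and QTL effect vectors (the two studies are
    # independent).
    cov_g = r * np.outer(sg, sg)
    cov_q = r * np.outer(sq, sq)

    jac_g = np.zeros((m, m + 1))
    jac_q = np.zeros((m, m + 1))
    for i in range(m):
        jac_g[i, i] = 1.0 / q[i]
        jac_g[i, m] = -1.0 / q[m]
        jac_q[i, i] = -g[i] / q[i] ** 2
        jac_q[i, m] = g[m] / q[m] ** 2
    cov_d = jac_g @ cov_g @ jac_g.T + jac_q @ cov_q @ jac_q.T

    d = g[:m] / q[:m] - g[m] / q[m]
    sd = np.sqrt(np.diag(cov_d))
    z_d = d / sd
    corr = cov_d / np.outer(sd, sd)

    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        warnings.warn("heidi_test: singular covariance, ridge-regularized")
        corr = corr + 1e-6 * np.eye(m)
        corr /= np.sqrt(np.outer(np.diag(corr), np.diag(corr)))
        chol = np.linalg.cholesky(corr)

    obs = float(np.sum(z_d**2))
    rng = np.random.default_rng(seed)
    draws = rng.standard_normal((n_draws, m)) @ chol.T
    null_stats = np.sum(draws**2, axis=1)
    p = float((1 + np.sum(null_stats >= obs)) / (n_draws + 1))
    return HeidiResult(p, m, "ok")


def assign_significance_tier(p_smr: float, m_tests_in_modality: int) -> str:
    """Most stringent significance tier achieved by one SMR association.

    Bonferroni (p < 0.05/m, strict), else suggestive (p < 1e-5, the
    conventional suggestive GWAS level), else nominal (p < 0.05), else none.
    """
    if m_tests_in_modality < 1:
        raise ValueError("m_tests_in_modality must be >= 1")
    if p_smr < 0.05 / m_tests_in_modality:
        return "bonferroni"
    if p_smr < 1e-5:
        return "suggestive"
    if p_smr < 0.05:
        return "nominal"
    return "none"


def heidi_pass(records: pd.DataFrame) -> pd.Series:
    """Boolean mask of records passing the HEIDI filter (p >= 0.05, >= 3 SNPs)."""
    return (records["p_heidi"] >= 0.05) & (records["n_snp_heidi"] >= 3)


def tier_genes(
    records: pd.DataFrame, concordance_modalities: tuple[str, ...] = ("eQTL", "pQTL")
) -> pd.DataFrame:
    """Stratify genes into the three-tier evidence schema.

    ``records`` needs columns gene, modality, b_smr, sig_tier (and optionally
    dataset); it is expected to be pre-filtered by HEIDI.  Tier 1 requires
    support from at least two modality/dataset combinations, directional
    concordance, and at least one Bonferroni-significant record; Tier 2 is
    any remaining gene with a Bonferroni record; Tier 3 is everything else.

    Directional concordance compares sign(b_smr) across the modalities named
    in ``concordance_modalities``; methylation signs are excluded by default
    because their direction is not interpretable against expression without
    annotation.
    """
    rows = []
    support_cols = (
        ["modality", "dataset"] if "dataset" in records.columns else ["modality"]
    )
    for gene, grp in records.groupby("gene", sort=True):
        n_support = grp[support_cols].drop_duplicates().shape[0]
        signs = np.sign(
            grp.loc[grp["modality"].isin(concordance_modalities), "b_smr"]
        )
        signs = signs[signs != 0]
        concordant = bool(signs.nunique() <= 1)
        any_bonf = bool((grp["sig_tier"] == "bonferroni").any())
        if n_support >= 2 and concordant and any_bonf:
            tier = 1
        elif any_bonf:
            tier = 2
        else:
            tier = 3
        rows.append(
            {
                "gene": gene,
                "n_modalities_supporting": n_support,
                "direction_concordant": concordant,
                "any_bonferroni": any_bonf,
                "tier": tier,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "n_modalities_supporting",
            "direction_concordant",
            "any_bonferroni",
            "tier",
        ],
    )
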