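"""Synthetic summary-data generators.

Every downstream stage of the pipeline consumes summary-level data: GWAS
summary statistics for the two-sample MR battery, per-locus QTL/GWAS z-score
tables with an LD matrix for SMR/HEIDI, log2 expression matrices for the
differential-expression and machine-learning stages, and cell-context DE
tables for the hotspot analysis.  The generators here emulate the statistical
structure those stages assume — instrument strength, horizontal pleiotropy,
shared-vs-linked causal variants, gene-wise variance heterogeneity, class
imbalance — without any individual-level genotype simulation.

All generators are deterministic under their config seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MRSimConfig",
    "QTLSimConfig",
    "ExprSimConfig",
    "simulate_mr_pair",
    "simulate_qtl_locus",
    "simulate_expression_study",
    "simulate_celltype_de_table",
    "make_ld_matrix",
]

# GWAS-SSF-like column vocabulary used throughout the package.
GWAS_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "EAF", "BETA", "SE", "P", "N"]

#: two-sided genome-wide significance threshold
GENOME_WIDE_P = 5e-8
_Z_GW = float(stats.norm.isf(GENOME_WIDE_P / 2.0))

_NONPALINDROMIC = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]
_PALINDROMIC = [("A", "T"), ("C", "G")]


@dataclass(frozen=True)
class MRSimConfig:
    """Configuration for a simulated exposure/outcome GWAS pair.

    The model per SNP j (standardized traits):

        sx_j = 1 / sqrt(2 p_j (1 - p_j) n_exp)       # exposure SE
        by_j = beta_causal * bx_j + alpha_j * I[j invalid] + eta_j

    with ``alpha_j ~ N(pleio_mean, pleio_sd^2)`` direct effects for the
    invalid fraction and ``eta_j ~ N(0, het_sd^2)`` extra heterogeneity.
    Observed effects carry sampling noise at the analytic SEs.
    """

    n_snps: int = 50
    n_exp: int = 200_000
    n_out: int = 200_000
    beta_causal: float = 0.0
    pleio_frac: float = 0.0
    pleio_mean: float = 0.0
    pleio_sd: float = 0.0
    het_sd: float = 0.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    palindromic_prob: float = 0.2
    allele_swap_prob: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.pleio_frac <= 1.0):
            raise ValueError("pleio_frac must lie in [0, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.n_exp < 2 or self.n_out < 2:
            raise ValueError("sample sizes must be >= 2")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")


@dataclass(frozen=True)
class QTLSimConfig:
    """Configuration for a simulated cis-QTL locus paired with a GWAS signal.

    ``model`` selects the causal architecture:

    - ``pleiotropy``: a single variant drives both the molecular trait and
      the complex trait (the SMR alternative that HEIDI should retain);
    - ``linkage``: two distinct variants in LD ``r2_linkage`` drive the QTL
      and the GWAS respectively (the confounding HEIDI should reject);
    - ``null``: the QTL is real but the GWAS carries no signal.
    """

    model: str = "pleiotropy"
    n_locus_snps: int = 30
    r2_linkage: float = 0.25
    b_qtl: float = 0.5
    b_gwas: float = 0.1
    n_qtl: int = 5_000
    n_gwas: int = 50_000
    ld_rho: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in {"pleiotropy", "linkage", "null"}:
            raise ValueError(f"unknown locus model {self.model!r}")
        if not (0.0 <= self.r2_linkage < 1.0):
            raise ValueError("r2_linkage must lie in [0, 1)")
        if self.n_locus_snps < 3:
            raise ValueError("n_locus_snps must be >= 3")


@dataclass(frozen=True)
class ExprSimConfig:
    """Configuration for a simulated two-group log2 expression study.

    Gene-wise residual variances are drawn from a scaled inverse chi-square
    prior with ``d0`` degrees of freedom and scale ``s0_sq`` — the same prior
    the empirical-Bayes moderation stage estimates — so moderation can be
    checked against planted truth.
    """

    n_genes: int = 1_000
    n_case: int = 30
    n_ctrl: int = 30
    de_frac: float = 0.1
    logfc_mean: float = 1.0
    logfc_sd: float = 0.2
    d0: float = 4.0
    s0_sq: float = 0.25
    batch_shift: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.de_frac <= 1.0):
            raise ValueError("de_frac must lie in [0, 1]")
        if self.d0 <= 0 or self.s0_sq <= 0:
            raise ValueError("d0 and s0_sq must be positive")
        if self.n_case < 2 or self.n_ctrl < 2:
            raise ValueError("each group needs at least 2 samples")


def _two_sided_p(z: np.ndarray) -> np.ndarray:
    return 2.0 * stats.norm.sf(np.abs(z))


def simulate_mr_pair(
    cfg: MRSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate an exposure GWAS, an outcome GWAS, and the generating truth.

    Every simulated instrument clears genome-wide significance in the
    exposure scan: true effects are drawn with a non-centrality safely above
    the threshold and, for the few draws whose sampling noise would push the
    observed z below it, the true effect is rescaled upward (keeping the
    realized noise) rather than rejection-sampled, so runtime is bounded and
    the truth record stores the realized effects.

    Returns ``(exposure, outcome, truth)`` where the tables are
    GWAS-SSF-like DataFrames and ``truth`` records ``beta_causal``, the
    invalid-instrument ids, their direct effects, and the realized true
    per-SNP effects.
    """
    rng = np.random.default_rng(cfg.seed)
    m = cfg.n_snps

    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
    sx = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * cfg.n_exp)
    sy = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * cfg.n_out)

    # True exposure effects: |z| targeted uniformly above the significance
    # threshold, sign random.
    sign = rng.choice([-1.0, 1.0], size=m)
    z_target = rng.uniform(_Z_GW + 2.0, _Z_GW + 12.0, size=m)
    bx_true = sign * z_target * sx

    e_x = rng.standard_normal(m)
    bx_hat = bx_true + e_x * sx
    weak = np.abs(bx_hat) / sx <= _Z_GW
    if np.any(weak):
        # rescale the true effect so the realized noise still clears threshold
        bx_true = bx_true.copy()
        bx_true[weak] = sign[weak] * (_Z_GW + 1.0 + np.abs(e_x[weak])) * sx[weak]
        bx_hat = bx_true + e_x * sx

    n_invalid = int(round(cfg.pleio_frac * m))
    invalid = np.zeros(m, dtype=bool)
    if n_invalid:
        invalid[rng.choice(m, size=n_invalid, replace=False)] = True
    alpha = np.zeros(m)
    alpha[invalid] = rng.normal(cfg.pleio_mean, cfg.pleio_sd, size=n_invalid)
    eta = rng.normal(0.0, cfg.het_sd, size=m) if cfg.het_sd > 0 else np.zeros(m)

    # direct effects are expressed relative to the exposure-increasing
    # allele, the orientation under which "directional" pleiotropy is defined
    by_true = cfg.beta_causal * bx_true + np.sign(bx_true) * alpha + eta
    by_hat = by_true + rng.standard_normal(m) * sy

    snp_ids = np.array([f"rs{100000 + j}" for j in range(m)])
    pal = rng.uniform(size=m) < cfg.palindromic_prob
    pair_idx = rng.integers(0, 2, size=m)
    a1 = np.where(
        pal,
        [_PALINDROMIC[i][0] for i in pair_idx],
        [_NONPALINDROMIC[i % 4][0] for i in rng.integers(0, 4, size=m)],
    )
    a2 = np.where(pal, [_PALINDROMIC[i][1] for i in pair_idx], "")
    # fill non-palindromic partners consistently
    for j in range(m):
        if not pal[j]:
            for x, y in _NONPALINDROMIC:
                if x == a1[j]:
                    a2[j] = y
                    break
    eaf = np.where(rng.uniform(size=m) < 0.5, maf, 1.0 - maf)

    exposure = pd.DataFrame(
        {
            "SNP": snp_ids,
            "CHR": "1",
            "BP": (np.arange(m) + 1) * 1_000_000,
            "A1": a1,
            "A2": a2,
            "EAF": eaf,
            "BETA": bx_hat,
            "SE": sx,
            "P": _two_sided_p(bx_hat / sx),
            "N": cfg.n_exp,
        }
    )

    # A fraction of outcome rows report the swapped allele pair, so the
    # harmonization sign-flip path is exercised on simulated data.
    swap = rng.uniform(size=m) < cfg.allele_swap_prob
    outcome = pd.DataFrame(
        {
            "SNP": snp_ids,
            "CHR": "1",
            "BP": (np.arange(m) + 1) * 1_000_000,
            "A1": np.where(swap, a2, a1),
            "A2": np.where(swap, a1, a2),
            "EAF": np.where(swap, 1.0 - eaf, eaf),
            "BETA": np.where(swap, -by_hat, by_hat),
            "SE": sy,
            "P": _two_sided_p(by_hat / sy),
            "N": cfg.n_out,
        }
    )

    zero_after_filter = not np.any(exposure["P"] < GENOME_WIDE_P)
    if zero_after_filter:  # pragma: no cover - construction prevents this
        raise RuntimeError(
            "no instrument passed genome-wide significance; raise n_exp"
        )

    truth = {
        "beta_causal": cfg.beta_causal,
        "invalid_snps": list(snp_ids[invalid]),
        "alpha": dict(zip(snp_ids[invalid], alpha[invalid])),
        "bx_true": dict(zip(snp_ids, bx_true)),
        "by_true": dict(zip(snp_ids, by_true)),
        "swapped_snps": list(snp_ids[swap]),
    }
    return exposure, outcome, truth


def make_ld_matrix(
    n: int,
    structure: str = "identity",
    rho: float = 0.9,
    block_size: int = 10,
    seed: int | None = None,
) -> np.ndarray:
    """Build a synthetic LD correlation matrix.

    ``structure`` is one of ``identity``, ``ar1`` (entries rho**|i-j|) or
    ``block`` (compound symmetry rho within consecutive blocks).  The result
    is validated to be symmetric, unit-diagonal and positive semi-definite.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if structure == "identity":
        ld = np.eye(n)
    elif structure == "ar1":
        if not (-1.0 < rho < 1.0):
            raise ValueError("ar1 requires |rho| < 1")
        idx = np.arange(n)
        ld = rho ** np.abs(idx[:, None] - idx[None, :])
    elif structure == "block":
        ld = np.eye(n)
        for start in range(0, n, block_size):
            stop = min(start + block_size, n)
            width = stop - start
            block = np.full((width, width), rho)
            np.fill_diagonal(block, 1.0)
            ld[start:stop, start:stop] = block
    else:
        raise ValueError(f"unknown LD structure {structure!r}")

    eigmin = float(np.linalg.eigvalsh(ld).min())
    if eigmin < -1e-10:
        raise ValueError(
            f"LD parameterization is not positive semi-definite (min eig {eigmin:.3g})"
        )
    return ld


def simulate_qtl_locus(
    cfg: QTLSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate one cis locus: QTL summary table, GWAS summary table, LD.

    Marginal z-scores follow the standard summary-statistic model
    ``z ~ MVN(R @ lambda, R)`` with ``R`` the LD correlation matrix and
    ``lambda`` the causal non-centrality vector (``b * sqrt(n)`` at each
    causal variant, zero elsewhere).  Betas and SEs are reported on the
    standardized scale ``b = z / sqrt(n)``, ``se = 1 / sqrt(n)``.
    """
    rng = np.random.default_rng(cfg.seed)
    m = cfg.n_locus_snps

    if cfg.model == "linkage" and cfg.r2_linkage > 0:
        # AR(1) with rho chosen so the two causal variants (2 steps apart)
        # have exactly r^2 = r2_linkage.
        rho = cfg.r2_linkage ** 0.25
    else:
        rho = cfg.ld_rho
    ld = make_ld_matrix(m, "ar1", rho=rho)

    c = m // 2
    lam_q = np.zeros(m)
    lam_g = np.zeros(m)
    if cfg.model == "pleiotropy":
        lam_q[c] = cfg.b_qtl * np.sqrt(cfg.n_qtl)
        lam_g[c] = cfg.b_gwas * np.sqrt(cfg.n_gwas)
    elif cfg.model == "linkage":
        c1, c2 = max(c - 1, 0), min(c + 1, m - 1)
        lam_q[c1] = cfg.b_qtl * np.sqrt(cfg.n_qtl)
        lam_g[c2] = cfg.b_gwas * np.sqrt(cfg.n_gwas)
    else:  # null: molecular trait only
        lam_q[c] = cfg.b_qtl * np.sqrt(cfg.n_qtl)

    chol = np.linalg.cholesky(ld + 1e-12 * np.eye(m))
    z_q = ld @ lam_q + chol @ rng.standard_normal(m)
    z_g = ld @ lam_g + chol @ rng.standard_normal(m)

    snp_ids = [f"rs{j:05d}" for j in range(m)]

    def _table(z: np.ndarray, n: int) -> pd.DataFrame:
        se = 1.0 / np.sqrt(n)
        return pd.DataFrame(
            {
                "SNP": snp_ids,
                "BETA": z * se,
                "SE": se,
                "P": _two_sided_p(z),
                "N": n,
            }
        )

    ld_df = pd.DataFrame(ld, index=snp_ids, columns=snp_ids)
    return _table(z_q, cfg.n_qtl), _table(z_g, cfg.n_gwas), ld_df


def simulate_expression_study(
    cfg: ExprSimConfig,
) -> tuple[pd.DataFrame, pd.Series, pd.Series, dict]:
    """Simulate a genes x samples log2 expression matrix with planted DE.

    Gene variances are scaled inverse chi-square ``d0 * s0_sq / chisq(d0)``;
    a ``de_frac`` fraction of genes get a log2 fold change drawn from
    ``N(logfc_mean, logfc_sd^2)`` with random sign, added to case samples.
    When ``batch_shift`` is set, samples are split into two batches balanced
    across groups and the second batch gains a constant offset.

    Returns ``(matrix, group_labels, batch_labels, truth)``.
    """
    rng = np.random.default_rng(cfg.seed)
    n_samp = cfg.n_case + cfg.n_ctrl
    genes = [f"G{g:05d}" for g in range(cfg.n_genes)]
    samples = [f"S{i:03d}" for i in range(n_samp)]

    s2 = cfg.d0 * cfg.s0_sq / rng.chisquare(cfg.d0, size=cfg.n_genes)
    base = rng.normal(7.0, 1.0, size=cfg.n_genes)

    x = base[:, None] + rng.standard_normal((cfg.n_genes, n_samp)) * np.sqrt(
        s2
    )[:, None]

    labels = pd.Series(
        ["case"] * cfg.n_case + ["control"] * cfg.n_ctrl,
        index=samples,
        name="group",
    )

    n_de = int(round(cfg.de_frac * cfg.n_genes))
    de_idx = rng.choice(cfg.n_genes, size=n_de, replace=False)
    lfc = rng.normal(cfg.logfc_mean, cfg.logfc_sd, size=n_de)
    lfc *= rng.choice([-1.0, 1.0], size=n_de)
    x[de_idx, : cfg.n_case] += lfc[:, None]

    # batches interleaved within each group so batch is never confounded
    batch = np.empty(n_samp, dtype=object)
    batch[: cfg.n_case] = np.where(
        np.arange(cfg.n_case) % 2 == 0, "batch1", "batch2"
    )
    batch[cfg.n_case :] = np.where(
        np.arange(cfg.n_ctrl) % 2 == 0, "batch1", "batch2"
    )
    batches = pd.Series(batch, index=samples, name="batch")
    if cfg.batch_shift is not None:
        x[:, batch == "batch2"] += cfg.batch_shift

    matrix = pd.DataFrame(x, index=genes, columns=samples)
    truth = {
        "de_genes": [genes[i] for i in de_idx],
        "log2fc": dict(zip((genes[i] for i in de_idx), lfc)),
        "s2_gene": dict(zip(genes, s2)),
        "d0": cfg.d0,
        "s0_sq": cfg.s0_sq,
    }
    return matrix, labels, batches, truth


def simulate_celltype_de_table(
    n_genes: int,
    contexts: list[tuple[str, str, str]],
    sig_pattern: dict,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a cell-context differential-expression table.

    ``contexts`` lists ``(cell_type, region, sex)`` triples. ``sig_pattern``
    maps a context triple to either an integer (that many genes, taken from
    the front of the gene list, planted significant with random logFC sign)
    or an explicit list of ``(gene_index, avg_logfc)`` pairs, which allows
    planting sign-discordant genes across contexts.

    Returns a tidy table with columns gene, cell_type, region, sex,
    avg_logfc, adj_p.
    """
    if not contexts:
        raise ValueError("contexts must be non-empty")
    rng = np.random.default_rng(seed)
    genes = [f"G{g:04d}" for g in range(n_genes)]
    rows = []
    for ctx in contexts:
        cell_type, region, sex = ctx
        spec = sig_pattern.get(ctx, 0)
        if isinstance(spec, int):
            planted = {
                i: float(rng.choice([-1.0, 1.0]) * rng.uniform(0.3, 1.0))
                for i in range(min(spec, n_genes))
            }
        else:
            planted = {int(i): float(lfc) for i, lfc in spec}
        for g_idx, gene in enumerate(genes):
            if g_idx in planted:
                logfc = planted[g_idx]
                adj_p = float(rng.uniform(1e-12, 0.04))
            else:
                logfc = float(rng.normal(0.0, 0.05))
                adj_p = float(rng.uniform(0.05, 1.0))
            rows.append(
                {
                    "gene": gene,
                    "cell_type": cell_type,
                    "region": region,
                    "sex": sex,
                    "avg_logfc": logfc,
                    "adj_p": adj_p,
                }
            )
    return pd.DataFrame(rows)
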