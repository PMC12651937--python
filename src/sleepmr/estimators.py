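"""Two-sample Mendelian randomization estimators and sensitivity diagnostics.

All estimators consume a harmonized instrument table (columns beta_exp,
se_exp, beta_out, se_out, SNP) and are written from first principles:

- ``ivw``: multiplicative random-effects inverse-variance weighted estimate
  (weighted regression through the origin, SE inflated by
  ``sqrt(max(1, Q/(k-1)))``); reduces to the Wald ratio at k = 1.
- ``egger``: weighted regression with a free intercept after orienting all
  exposure effects non-negative; the intercept estimates average directional
  pleiotropy.
- ``weighted_median``: weight-interpolated median of per-SNP Wald ratios,
  consistent when up to half the instrument weight is invalid; SE by seeded
  parametric bootstrap.
- ``cochran_q``: heterogeneity of per-SNP ratios around a pooled estimate.
- ``radial_outliers``: per-SNP contribution to the radial Q compared with a
  (Bonferroni-adjusted) chi-square(1) quantile.
- ``presso_global``: simulation-based global pleiotropy test on the observed
  leave-one-out residual sum of squares.

Ratio SEs use the first-order delta method ``se_out / |beta_exp|``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import instruments as instr_mod
from .simulate import GENOME_WIDE_P

__all__ = [
    "MRFit",
    "EggerFit",
    "QResult",
    "RadialResult",
    "MRSuiteResult",
    "MRSuiteConfig",
    "ivw",
    "egger",
    "weighted_median",
    "cochran_q",
    "radial_outliers",
    "presso_global",
    "run_mr_suite",
]


@dataclass(frozen=True)
class MRFit:
    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int


@dataclass(frozen=True)
class EggerFit:
    slope: MRFit
    intercept: float
    intercept_se: float
    intercept_p: float


@dataclass(frozen=True)
class QResult:
    q: float
    df: int
    pval: float


@dataclass(frozen=True)
class RadialResult:
    outlier_snps: list[str]
    refit: MRFit | None


_Z95 = float(stats.norm.isf(0.025))


def _check(instr: pd.DataFrame, min_snp: int, method: str) -> None:
    if len(instr) < min_snp:
        raise ValueError(f"{method} requires at least {min_snp} instruments")
    if (instr["se_out"] <= 0).any() or (instr["se_exp"] <= 0).any():
        raise ValueError(f"{method}: all standard errors must be positive")


def _fit(method, est, se, k, dist="norm", df=None) -> MRFit:
    if se == 0.0:
        p = 1.0 if est == 0.0 else 0.0
        lo = hi = est
    else:
        z = est / se
        if dist == "t":
            p = float(2.0 * stats.t.sf(abs(z), df))
            crit = float(stats.t.isf(0.025, df))
        else:
            p = float(2.0 * stats.norm.sf(abs(z)))
            crit = _Z95
        lo, hi = est - crit * se, est + crit * se
    return MRFit(method, float(est), float(se), float(lo), float(hi), max(p, 5e-324), k)


def ivw(instr: pd.DataFrame) -> MRFit:
    """Random-effects IVW estimate (Wald ratio when a single SNP is given)."""
    _check(instr, 1, "ivw")
    bx = instr["beta_exp"].to_numpy(float)
    by = instr["beta_out"].to_numpy(float)
    sy = instr["se_out"].to_numpy(float)
    k = len(bx)
    if k == 1:
        est = by[0] / bx[0]
        se = sy[0] / abs(bx[0])
        return _fit("ivw", est, se, 1)
    w = 1.0 / sy**2
    denom = float(np.sum(w * bx**2))
    est = float(np.sum(w * bx * by)) / denom
    q = float(np.sum(w * (by - est * bx) ** 2))
    phi = max(1.0, q / (k - 1))
    se = np.sqrt(phi / denom)
    return _fit("ivw", est, se, k)


def egger(instr: pd.DataFrame) -> EggerFit:
    """MR-Egger regression; intercept tests directional pleiotropy.

    Exposure effects are oriented non-negative first (flipping the paired
    outcome effect), the InSIDE sign convention.  Inference uses a t
    distribution on k - 2 df with multiplicative over-dispersion floored at 1.
    """
    _check(instr, 3, "egger")
    bx = instr["beta_exp"].to_numpy(float).copy()
    by = instr["beta_out"].to_numpy(float).copy()
    sy = instr["se_out"].to_numpy(float)
    flip = bx < 0
    bx[flip] *= -1.0
    by[flip] *= -1.0
    k = len(bx)
    w = 1.0 / sy**2

    sw = w.sum()
    swx = float(np.sum(w * bx))
    swx2 = float(np.sum(w * bx**2))
    swy = float(np.sum(w * by))
    swxy = float(np.sum(w * bx * by))
    det = sw * swx2 - swx**2
    if det <= 0:
        raise ValueError("egger: degenerate design (constant beta_exp)")
    slope = (sw * swxy - swx * swy) / det
    icept = (swx2 * swy - swx * swxy) / det

    resid = by - icept - slope * bx
    rss = float(np.sum(w * resid**2))
    phi = max(1.0, rss / (k - 2))
    se_slope = np.sqrt(phi * sw / det)
    se_icept = np.sqrt(phi * swx2 / det)

    slope_fit = _fit("egger", slope, se_slope, k, dist="t", df=k - 2)
    if se_icept == 0.0:
        p_icept = 1.0 if icept == 0.0 else 0.0
    else:
        p_icept = float(2.0 * stats.t.sf(abs(icept / se_icept), k - 2))
    return EggerFit(slope_fit, float(icept), float(se_icept), p_icept)


def _wm_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w) - 0.5 * w
    if s[0] >= 0.5:
        return float(r[0])
    if s[-1] <= 0.5:
        return float(r[-1])
    j = int(np.searchsorted(s, 0.5))
    # linear interpolation between bracketing order statistics
    return float(
        r[j - 1] + (r[j] - r[j - 1]) * (0.5 - s[j - 1]) / (s[j] - s[j - 1])
    )


def weighted_median(
    instr: pd.DataFrame, n_boot: int = 1000, seed: int = 42
) -> MRFit:
    """Weighted-median MR estimate with parametric-bootstrap SE."""
    _check(instr, 3, "weighted_median")
    bx = instr["beta_exp"].to_numpy(float)
    by = instr["beta_out"].to_numpy(float)
    sx = instr["se_exp"].to_numpy(float)
    sy = instr["se_out"].to_numpy(float)
    k = len(bx)

    ratios = by / bx
    w = (np.abs(bx) / sy) ** 2  # 1 / se(ratio)^2, first-order delta method
    est = _wm_point(ratios, w)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxb = bx + rng.standard_normal(k) * sx
        byb = by + rng.standard_normal(k) * sy
        bxb[bxb == 0.0] = 1e-300
        boots[b] = _wm_point(byb / bxb, (np.abs(bxb) / sy) ** 2)
    se = float(np.std(boots, ddof=1))
    return _fit("weighted_median", est, se, k)


def cochran_q(instr: pd.DataFrame, pooled_estimate: float) -> QResult:
    """Cochran's Q across per-SNP Wald ratios around ``pooled_estimate``."""
    if len(instr) < 2:
        raise ValueError("cochran_q undefined for fewer than 2 instruments")
    bx = instr["beta_exp"].to_numpy(float)
    by = instr["beta_out"].to_numpy(float)
    sy = instr["se_out"].to_numpy(float)
    ratios = by / bx
    w = (np.abs(bx) / sy) ** 2
    q = float(np.sum(w * (ratios - pooled_estimate) ** 2))
    df = len(bx) - 1
    return QResult(q, df, float(stats.chi2.sf(q, df)))


def radial_outliers(
    instr: pd.DataFrame, alpha: float = 0.05, bonferroni: bool = True
) -> RadialResult:
    """Flag SNPs whose radial-Q contribution exceeds a chi-square(1) quantile.

    The per-SNP contribution is ``w_j (ratio_j - ivw)^2`` — the j-th term of
    Cochran's Q around the IVW estimate.  With ``bonferroni`` the quantile is
    taken at alpha / k.  A refit excluding the flagged SNPs is attached when
    any remain.
    """
    _check(instr, 3, "radial_outliers")
    fit = ivw(instr)
    bx = instr["beta_exp"].to_numpy(float)
    by = instr["beta_out"].to_numpy(float)
    sy = instr["se_out"].to_numpy(float)
    k = len(bx)
    qj = ((np.abs(bx) / sy) ** 2) * (by / bx - fit.estimate) ** 2
    thresh = stats.chi2.isf(alpha / k if bonferroni else alpha, 1)
    mask = qj > thresh
    outliers = sorted(instr.loc[mask, "SNP"].tolist())
    refit = None
    if outliers and (~mask).sum() >= 1:
        refit = ivw(instr.loc[~mask])
    return RadialResult(outliers, refit)


def presso_global(
    instr: pd.DataFrame, n_sim: int = 1000, seed: int = 42
) -> float:
    """Global pleiotropy test: observed leave-one-out residual sum of squares
    against its parametric null distribution.

    For each SNP j the expected outcome effect is ``beta_exp_j * ivw_{-j}``
    (IVW estimate without SNP j); RSS_obs sums the squared deviations.  The
    null distribution is built by redrawing both effect vectors from their
    fitted sampling model and recomputing the statistic; the empirical p uses
    +1 smoothing.
    """
    import warnings

    _check(instr, 4, "presso_global")
    if n_sim < 10:
        raise ValueError("presso_global requires n_sim >= 10")
    if n_sim < 100:
        warnings.warn("presso_global: n_sim < 100 gives a coarse p-value")

    bx = instr["beta_exp"].to_numpy(float)
    by = instr["beta_out"].to_numpy(float)
    sx = instr["se_exp"].to_numpy(float)
    sy = instr["se_out"].to_numpy(float)
    k = len(bx)
    w = 1.0 / sy**2

    def _loo_rss(bxm: np.ndarray, bym: np.ndarray) -> np.ndarray:
        # vectorized over rows (simulations); bxm, bym are (n, k)
        s1 = np.sum(w * bxm * bym, axis=1, keepdims=True)
        s2 = np.sum(w * bxm**2, axis=1, keepdims=True)
        loo = (s1 - w * bxm * bym) / (s2 - w * bxm**2)
        return np.sum((bym - loo * bxm) ** 2, axis=1)

    rss_obs = float(_loo_rss(bx[None, :], by[None, :])[0])

    # fitted model for the null draws: outcome effects centered on the IVW line
    beta_hat = ivw(instr).estimate
    rng = np.random.default_rng(seed)
    bx_sim = bx + rng.standard_normal((n_sim, k)) * sx
    by_sim = beta_hat * bx[None, :] + rng.standard_normal((n_sim, k)) * sy
    rss_null = _loo_rss(bx_sim, by_sim)
    return float((1 + np.sum(rss_null >= rss_obs)) / (n_sim + 1))


@dataclass(frozen=True)
class MRSuiteConfig:
    p_instrument: float = GENOME_WIDE_P
    clump_r2: float = 0.001
    clump_window_kb: float = 10_000.0
    min_snps: int = 5
    n_boot: int = 1000
    presso_n_sim: int = 1000
    seed: int = 42


@dataclass
class MRSuiteResult:
    pair_id: str
    direction: str
    excluded: bool = False
    exclusion_reason: str | None = None
    fits: dict[str, MRFit] = field(default_factory=dict)
    egger_intercept: float | None = None
    egger_intercept_p: float | None = None
    cochran_q: float | None = None
    q_df: int | None = None
    q_pval: float | None = None
    presso_global_p: float | None = None
    radial_outlier_ids: list[str] = field(default_factory=list)
    reverse_ivw_p: float | None = None
    funnel: dict[str, int] = field(default_factory=dict)
    instrument_strength: instr_mod.InstrumentStrength | None = None


def _one_direction(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    ld,
    cfg: MRSuiteConfig,
    pair_id: str,
    direction: str,
) -> MRSuiteResult:
    res = MRSuiteResult(pair_id=pair_id, direction=direction)
    selected = exposure.loc[exposure["P"] < cfg.p_instrument]
    res.funnel["selected"] = len(selected)
    if selected.empty:
        res.excluded = True
        res.exclusion_reason = "no_significant_instruments"
        return res

    if ld is not None:
        sub = (
            ld.loc[selected["SNP"], selected["SNP"]]
            if isinstance(ld, pd.DataFrame)
            else ld
        )
        from .instruments import ld_clump

        kept_ids = ld_clump(selected, sub, cfg.clump_r2, cfg.clump_window_kb)
        selected = selected.loc[selected["SNP"].isin(kept_ids)]
    res.funnel["clumped"] = len(selected)

    from .instruments import check_min_snps, harmonize

    harmonized, drops = harmonize(selected, outcome)
    res.funnel["harmonized"] = len(harmonized)
    res.funnel["harmonization_drops"] = len(drops)

    check = check_min_snps(harmonized, cfg.min_snps)
    if not check.passed:
        res.excluded = True
        res.exclusion_reason = check.reason
        return res

    if not harmonized["eaf_exp"].isna().any():
        n_exp = int(exposure["N"].iloc[0]) if "N" in exposure else 0
        k = len(harmonized)
        if n_exp > k + 1:
            r2 = instr_mod.instrument_r2(harmonized)
            if r2 < 1.0:
                res.instrument_strength = instr_mod.compute_f_statistic(
                    r2, n_exp, k
                )

    ivw_fit = ivw(harmonized)
    res.fits["ivw"] = ivw_fit
    try:
        eg = egger(harmonized)
        res.fits["egger"] = eg.slope
        res.egger_intercept = eg.intercept
        res.egger_intercept_p = eg.intercept_p
    except ValueError:
        pass
    try:
        res.fits["weighted_median"] = weighted_median(
            harmonized, n_boot=cfg.n_boot, seed=cfg.seed
        )
    except ValueError:
        pass
    if len(harmonized) >= 2:
        qres = cochran_q(harmonized, ivw_fit.estimate)
        res.cochran_q, res.q_df, res.q_pval = qres.q, qres.df, qres.pval
    if len(harmonized) >= 3:
        res.radial_outlier_ids = radial_outliers(harmonized).outlier_snps
    if len(harmonized) >= 4:
        res.presso_global_p = presso_global(
            harmonized, n_sim=cfg.presso_n_sim, seed=cfg.seed
        )
    return res


def run_mr_suite(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    ld: pd.DataFrame | None = None,
    config: MRSuiteConfig | None = None,
    pair_id: str = "pair",
    direction: str = "forward",
) -> MRSuiteResult:
    """Full MR analysis of one exposure-outcome pair.

    Chains instrument selection, LD clumping, harmonization and the minimum
    SNP-count check, then runs every estimator on the identical harmonized
    set.  The swapped direction (outcome as exposure) is also analysed to
    populate ``reverse_ivw_p``; if the swapped direction yields no usable
    instruments the field stays None.
    """
    cfg = config or MRSuiteConfig()
    res = _one_direction(exposure, outcome, ld, cfg, pair_id, direction)
    rev = _one_direction(outcome, exposure, ld, cfg, pair_id, direction + ":reverse")
    if not rev.excluded and "ivw" in rev.fits:
        res.reverse_ivw_p = rev.fits["ivw"].pval
    return res
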