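"""Hierarchical prioritization of MR results.

The battery of exposure-outcome pairs is stratified by combining two streams
of evidence: a global Benjamini-Hochberg FDR over all primary IVW p-values
(both directions pooled), and a four-condition robustness screen —
(1) nominally significant IVW effect, (2) weighted-median estimate with a
concordant direction, (3) non-significant MR-Egger intercept, and
(4) non-significant Cochran's Q.  Pairs passing both the q < 0.05 threshold
and the screen are High-Confidence; pairs passing the screen with nominal
IVW significance only are Suggestive.

A significant reverse-direction IVW is reported alongside the tier as a
caveat; it demotes the tier only in strict mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ScreenFlags",
    "global_fdr",
    "robustness_screen",
    "classify_association",
    "select_representative",
    "summarize_asymmetry",
    "TIERS",
]

TIERS = ("high_confidence", "suggestive", "non_robust", "null")


@dataclass(frozen=True)
class ScreenFlags:
    ivw_nominal: bool
    wm_concordant: bool
    egger_clean: bool
    q_clean: bool
    reasons: tuple[str, ...] = ()

    def all_pass(self) -> bool:
        return (
            self.ivw_nominal
            and self.wm_concordant
            and self.egger_clean
            and self.q_clean
        )


def global_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg q-values over the pooled primary IVW tests."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def robustness_screen(suite) -> ScreenFlags:
    """Evaluate the four-condition robustness screen on an MR suite result.

    Missing components (weighted median or Egger skipped for too few SNPs,
    Q undefined) fail their condition with a recorded reason.
    """
    reasons: list[str] = []
    ivw_fit = suite.fits.get("ivw")
    if ivw_fit is None:
        return ScreenFlags(False, False, False, False, ("no_ivw_fit",))
    ivw_nominal = ivw_fit.pval < 0.05

    wm = suite.fits.get("weighted_median")
    if wm is None:
        wm_concordant = False
        reasons.append("weighted_median_unavailable")
    else:
        # sign agreement only; a zero estimate is concordant with anything
        wm_concordant = (
            np.sign(wm.estimate) == np.sign(ivw_fit.estimate)
            or wm.estimate == 0.0
            or ivw_fit.estimate == 0.0
        )

    if suite.egger_intercept_p is None:
        egger_clean = False
        reasons.append("egger_unavailable")
    else:
        egger_clean = suite.egger_intercept_p > 0.05

    if suite.q_pval is None:
        q_clean = False
        reasons.append("cochran_q_unavailable")
    else:
        q_clean = suite.q_pval > 0.05

    return ScreenFlags(
        bool(ivw_nominal),
        bool(wm_concordant),
        bool(egger_clean),
        bool(q_clean),
        tuple(reasons),
    )


def classify_association(
    ivw_p: float,
    q_value: float,
    flags: ScreenFlags,
    reverse_ivw_p: float | None = None,
    strict_reverse: bool = False,
) -> str:
    """Assign the evidence tier for one exposure-outcome pair.

    Any failed robustness condition (beyond IVW nominal significance itself)
    gives ``non_robust``; a clean screen without nominal IVW significance is
    ``null``; otherwise q < 0.05 separates ``high_confidence`` from
    ``suggestive``.  With ``strict_reverse`` a significant reverse-direction
    IVW (p < 0.05) acts as a fifth screen condition.
    """
    if not (flags.wm_concordant and flags.egger_clean and flags.q_clean):
        return "non_robust"
    if strict_reverse and reverse_ivw_p is not None and reverse_ivw_p < 0.05:
        return "non_robust"
    if ivw_p >= 0.05:
        return "null"
    return "high_confidence" if q_value < 0.05 else "suggestive"


_TIER_RANK = {"high_confidence": 0, "suggestive": 1}


def select_representative(
    classifications: pd.DataFrame, category_map: dict[str, str]
) -> dict[str, str | None]:
    """Pick one representative pair per phenotypic category.

    ``classifications`` needs columns pair_id, tier, q_value, ivw_p, n_snp.
    Within a category only screened tiers (high_confidence, suggestive) are
    eligible, ranked by tier, then ascending q, ascending IVW p, descending
    n_snp, and finally lexicographic pair_id.  Categories with no screened
    pair map to None.
    """
    missing = set(classifications["pair_id"]) - set(category_map)
    if missing:
        raise ValueError(f"pairs without a category: {sorted(missing)[:3]}")
    df = classifications.copy()
    df["category"] = df["pair_id"].map(category_map)
    out: dict[str, str | None] = {c: None for c in category_map.values()}
    eligible = df[df["tier"].isin(_TIER_RANK)]
    for cat, grp in eligible.groupby("category"):
        ranked = grp.assign(_tier_rank=grp["tier"].map(_TIER_RANK)).sort_values(
            ["_tier_rank", "q_value", "ivw_p", "n_snp", "pair_id"],
            ascending=[True, True, True, False, True],
            kind="mergesort",
        )
        out[cat] = ranked["pair_id"].iloc[0]
    return out


def summarize_asymmetry(classifications: pd.DataFrame) -> dict:
    """Tier-by-direction contingency and the high-confidence asymmetry.

    ``classifications`` needs columns direction and tier.  The asymmetry
    statistic is the difference in high-confidence counts between the two
    direction labels (first minus second in sorted order).
    """
    table = pd.DataFrame(0, index=list(TIERS), columns=[])
    if not classifications.empty:
        table = (
            classifications.groupby(["tier", "direction"])
            .size()
            .unstack(fill_value=0)
            .reindex(TIERS, fill_value=0)
        )
    directions = sorted(table.columns)
    hc = table.loc["high_confidence"] if "high_confidence" in table.index else None
    if len(directions) == 2 and hc is not None:
        asym = int(hc[directions[0]] - hc[directions[1]])
    else:
        asym = 0
    return {"contingency": table, "asymmetry_high_confidence": asym}
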