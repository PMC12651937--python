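"""Instrument selection, LD clumping, allele harmonization, and strength diagnostics.

Operates on GWAS-SSF-like DataFrames (columns SNP, CHR, BP, A1, A2, EAF,
BETA, SE, P, N).  Harmonized exposure/outcome pairs are DataFrames with
columns SNP, beta_exp, se_exp, beta_out, se_out, eaf_exp plus provenance
columns (``flipped``); dropped rows are reported separately with a reason.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "select_instruments",
    "ld_clump",
    "harmonize",
    "check_min_snps",
    "instrument_r2",
    "compute_f_statistic",
    "InstrumentCheck",
    "InstrumentStrength",
]

#: EAF window in which a palindromic SNP's strand cannot be resolved
AMBIGUOUS_EAF = (0.42, 0.58)

_PALINDROMIC_PAIRS = {frozenset({"A", "T"}), frozenset({"C", "G"})}


@dataclass(frozen=True)
class InstrumentCheck:
    passed: bool
    n_snps: int
    reason: str | None = None


@dataclass(frozen=True)
class InstrumentStrength:
    """Aggregate instrument-strength diagnostics for one exposure."""

    r2_total: float
    k: int
    n: int
    f_stat: float

    @property
    def weak(self) -> bool:
        """True unless F exceeds the conventional F > 10 threshold (strict)."""
        return not (self.f_stat > 10.0)


def select_instruments(
    table: pd.DataFrame, p_threshold: float = 5e-8
) -> pd.DataFrame:
    """Keep rows associated at ``p < p_threshold`` (strict), order preserved."""
    if table.empty:
        raise ValueError("instrument table is empty")
    return table.loc[table["P"] < p_threshold].copy()


def ld_clump(
    variants: pd.DataFrame,
    ld: pd.DataFrame | np.ndarray,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000.0,
) -> list[str]:
    """Greedy LD clumping.

    Sort ascending by p-value (ties: smaller genomic position first, then
    SNP id); accept the best remaining variant; discard any unaccepted
    variant with r^2 above ``r2_threshold`` to an accepted variant that lies
    within ``window_kb`` on the same chromosome; repeat.  Returns accepted
    SNP ids in acceptance order.
    """
    if isinstance(ld, np.ndarray):
        ld = pd.DataFrame(
            ld, index=variants["SNP"].tolist(), columns=variants["SNP"].tolist()
        )
    missing = [s for s in variants["SNP"] if s not in ld.index]
    if missing:
        raise ValueError(f"variant missing from LD matrix: {missing[0]}")

    order = variants.sort_values(
        ["P", "BP", "SNP"], kind="mergesort"
    ).reset_index(drop=True)
    window_bp = window_kb * 1_000.0

    accepted: list[str] = []
    acc_rows: list[pd.Series] = []
    removed: set[str] = set()
    for _, row in order.iterrows():
        snp = row["SNP"]
        if snp in removed:
            continue
        conflict = False
        for acc in acc_rows:
            same_chr = str(row["CHR"]) == str(acc["CHR"])
            close = abs(float(row["BP"]) - float(acc["BP"])) <= window_bp
            r2 = float(ld.loc[snp, acc["SNP"]]) ** 2
            if same_chr and close and r2 > r2_threshold:
                conflict = True
                break
        if conflict:
            removed.add(snp)
        else:
            accepted.append(snp)
            acc_rows.append(row)
    return accepted


def _is_palindromic(a1: str, a2: str) -> bool:
    return frozenset({str(a1).upper(), str(a2).upper()}) in _PALINDROMIC_PAIRS


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    ambiguous_eaf: tuple[float, float] = AMBIGUOUS_EAF,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align exposure and outcome effects to a consistent effect allele.

    Outcome rows whose allele pair is swapped relative to the exposure have
    their beta sign flipped and EAF complemented.  Palindromic SNPs (A/T or
    C/G) are dropped when the exposure EAF lies in the ambiguity window
    (inclusive) or is missing; allele pairs that match neither orientation
    are dropped as incompatible.

    Returns ``(harmonized, dropped)``: the harmonized pair table
    (SNP, beta_exp, se_exp, beta_out, se_out, eaf_exp, flipped) and a table
    of dropped SNPs with a ``reason`` column.
    """
    for name, tab in (("exposure", exposure), ("outcome", outcome)):
        if tab["SNP"].duplicated().any():
            dup = tab.loc[tab["SNP"].duplicated(), "SNP"].iloc[0]
            raise ValueError(f"duplicate snp_id {dup!r} in {name} table")

    out_idx = outcome.set_index("SNP")
    kept, dropped = [], []
    lo, hi = ambiguous_eaf
    for _, ex in exposure.iterrows():
        snp = ex["SNP"]
        if snp not in out_idx.index:
            dropped.append({"SNP": snp, "reason": "missing_in_outcome"})
            continue
        ou = out_idx.loc[snp]
        e1, e2 = str(ex["A1"]).upper(), str(ex["A2"]).upper()
        o1, o2 = str(ou["A1"]).upper(), str(ou["A2"]).upper()

        if _is_palindromic(e1, e2):
            eaf = ex.get("EAF", np.nan)
            if pd.isna(eaf) or (lo <= float(eaf) <= hi):
                dropped.append({"SNP": snp, "reason": "palindromic_ambiguous"})
                continue

        if (o1, o2) == (e1, e2):
            beta_out, flipped = float(ou["BETA"]), False
        elif (o1, o2) == (e2, e1):
            beta_out, flipped = -float(ou["BETA"]), True
        else:
            dropped.append({"SNP": snp, "reason": "incompatible_alleles"})
            continue

        kept.append(
            {
                "SNP": snp,
                "beta_exp": float(ex["BETA"]),
                "se_exp": float(ex["SE"]),
                "beta_out": beta_out,
                "se_out": float(ou["SE"]),
                "eaf_exp": float(ex["EAF"]) if "EAF" in ex else np.nan,
                "flipped": flipped,
            }
        )

    harmonized = pd.DataFrame(
        kept,
        columns=[
            "SNP",
            "beta_exp",
            "se_exp",
            "beta_out",
            "se_out",
            "eaf_exp",
            "flipped",
        ],
    )
    drop_df = pd.DataFrame(dropped, columns=["SNP", "reason"])
    return harmonized, drop_df


def check_min_snps(
    instruments: pd.DataFrame | int, minimum: int = 5
) -> InstrumentCheck:
    """Exclude exposure-outcome pairs with fewer than ``minimum`` harmonized SNPs."""
    n = instruments if isinstance(instruments, int) else len(instruments)
    if n == 0:
        return InstrumentCheck(False, 0, "no_harmonized_snps")
    if n < minimum:
        return InstrumentCheck(False, n, "below_min_snps")
    return InstrumentCheck(True, n)


def instrument_r2(instruments: pd.DataFrame) -> float:
    """Variance in the exposure explained by the instruments.

    Standardized-trait convention: per SNP ``2 p (1-p) beta^2`` summed over
    instruments, with p the effect-allele frequency.
    """
    eaf = instruments["eaf_exp"].to_numpy(dtype=float)
    beta = instruments["beta_exp"].to_numpy(dtype=float)
    if np.isnan(eaf).any():
        raise ValueError("instrument_r2 requires EAF for every instrument")
    return float(np.sum(2.0 * eaf * (1.0 - eaf) * beta**2))


def compute_f_statistic(r2_total: float, n: int, k: int) -> InstrumentStrength:
    """Instrument-strength F statistic, F = R^2 (N - K - 1) / [K (1 - R^2)]."""
    if not (0.0 <= r2_total < 1.0):
        raise ValueError("r2_total must lie in [0, 1)")
    if k < 1:
        raise ValueError("k must be >= 1")
    if n <= k + 1:
        raise ValueError("requires n > k + 1")
    f = r2_total * (n - k - 1) / (k * (1.0 - r2_total))
    return InstrumentStrength(r2_total=r2_total, k=k, n=n, f_stat=f)
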