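"""Composite evidence scoring and single-cell hotspot analysis.

The Final Evidence Score combines the machine-learning consensus importance
with cross-cohort differential-expression support:

    final_score = overall_importance + 0.5 * de_sig_count

where ``de_sig_count`` is the number of independent cohorts in which the
gene is nominally significant (p < 0.05, strict).  The single-cell Evidence
Score integrates, per gene, the breadth of significant cell-context DE hits,
the maximum absolute logFC, and the (capped) minimum -log10 adjusted p,
each min-max normalized across genes and combined as a weighted sum.
Candidates are selected at a strict score threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "de_significance_count",
    "final_evidence_score",
    "rank_evidence",
    "hotspot_counts",
    "single_cell_evidence_score",
    "select_candidates",
    "sign_discordance",
]

CONTEXT_COLS = ["cell_type", "region", "sex"]


def de_significance_count(
    gene: str, de_tables: dict[str, pd.DataFrame], use_adjusted: bool = False
) -> int:
    """Number of cohorts where ``gene`` is significant at p < 0.05 (strict).

    ``de_tables`` maps cohort name to a DE table indexed by gene with a
    ``pval`` (and ``adj_p``) column; cohorts lacking the gene contribute 0.
    """
    col = "adj_p" if use_adjusted else "pval"
    count = 0
    for table in de_tables.values():
        if gene in table.index and float(table.loc[gene, col]) < 0.05:
            count += 1
    return count


def final_evidence_score(overall_importance: float, de_sig_count: int) -> float:
    """Exact composite: importance + 0.5 per nominally significant cohort."""
    if not (0.0 <= overall_importance <= 1.0):
        raise ValueError("overall_importance must lie in [0, 1]")
    if de_sig_count < 0 or int(de_sig_count) != de_sig_count:
        raise ValueError("de_sig_count must be a non-negative integer")
    return float(overall_importance) + 0.5 * int(de_sig_count)


def rank_evidence(
    importance: pd.Series, de_tables: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """Final Evidence Score table for every gene in the importance profile.

    Descending score; ties broken by importance, then gene symbol.
    """
    rows = []
    for gene, imp in importance.items():
        count = de_significance_count(gene, de_tables)
        rows.append(
            {
                "gene": gene,
                "overall_importance": float(imp),
                "de_sig_count": count,
                "final_score": final_evidence_score(float(imp), count),
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["final_score", "overall_importance", "gene"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


def hotspot_counts(
    table: pd.DataFrame, alpha: float = 0.05, logfc_min: float = 0.0
) -> pd.DataFrame:
    """Rank (cell_type, region, sex) contexts by significant-gene counts.

    A gene counts toward a context when adj_p < alpha (strict) and
    |avg_logfc| >= logfc_min.  Ties are broken by context label.
    """
    if table.empty:
        return pd.DataFrame(columns=CONTEXT_COLS + ["n_significant"])
    sig = table[
        (table["adj_p"] < alpha) & (table["avg_logfc"].abs() >= logfc_min)
    ]
    counts = (
        sig.groupby(CONTEXT_COLS, sort=True)
        .size()
        .reindex(
            table[CONTEXT_COLS].drop_duplicates().apply(tuple, axis=1).pipe(
                pd.MultiIndex.from_tuples, names=CONTEXT_COLS
            ),
            fill_value=0,
        )
        .rename("n_significant")
        .reset_index()
    )
    return counts.sort_values(
        ["n_significant"] + CONTEXT_COLS,
        ascending=[False, True, True, True],
        kind="mergesort",
    ).reset_index(drop=True)


def single_cell_evidence_score(
    table: pd.DataFrame,
    alpha: float = 0.05,
    cap_neglogp: float = 300.0,
    weights: tuple[float, float, float] = (1.0, 0.5, 0.5),
) -> pd.DataFrame:
    """Per-gene single-cell Evidence Score.

    Components per gene: number of significant (adj_p < alpha) context hits,
    maximum |avg_logfc|, and minimum -log10(adj_p) capped at ``cap_neglogp``
    (adjusted p of exactly zero maps to the cap).  Components are min-max
    normalized across genes and combined as a weighted sum.  With a single
    gene the normalization is degenerate: all components are set to 1 with a
    warning.
    """
    if table.empty:
        raise ValueError("single_cell_evidence_score needs at least one gene")
    rows = []
    for gene, grp in table.groupby("gene", sort=True):
        sig = grp[grp["adj_p"] < alpha]
        with np.errstate(divide="ignore"):
            neglog = -np.log10(np.maximum(grp["adj_p"].to_numpy(float), 0.0))
        rows.append(
            {
                "gene": gene,
                "n_sig_hits": len(sig),
                "max_abs_logfc": float(grp["avg_logfc"].abs().max()),
                "min_neglog10_adjp": float(
                    np.minimum(np.max(neglog), cap_neglogp)
                ),
            }
        )
    df = pd.DataFrame(rows)
    comps = ["n_sig_hits", "max_abs_logfc", "min_neglog10_adjp"]
    if len(df) == 1:
        warnings.warn(
            "single gene input: min-max normalization degenerate, components set to 1"
        )
        norm = pd.DataFrame(1.0, index=df.index, columns=comps)
    else:
        norm = pd.DataFrame(index=df.index)
        for c in comps:
            v = df[c].to_numpy(float)
            span = v.max() - v.min()
            norm[c] = (v - v.min()) / span if span > 0 else 0.0
    w = np.asarray(weights, dtype=float)
    df["sc_score"] = (norm[comps].to_numpy() * w).sum(axis=1)
    return df.sort_values(
        ["sc_score", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def select_candidates(
    scores: pd.DataFrame, threshold: float = 1.0, score_col: str = "sc_score"
) -> list[str]:
    """Genes with score strictly above ``threshold``, ordered by score."""
    if scores.empty:
        return []
    passing = scores[scores[score_col] > threshold]
    return passing.sort_values(
        [score_col, "gene"], ascending=[False, True], kind="mergesort"
    )["gene"].tolist()


def sign_discordance(
    table: pd.DataFrame,
    alpha: float = 0.05,
    cell_classes: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Context pairs with significant, opposite-signed logFC for one gene.

    Both contexts must satisfy adj_p < alpha.  When ``cell_classes`` maps
    cell types to classes (e.g. neuron vs glia), a ``neuron_glia`` flag marks
    pairs whose contexts fall in different classes.
    """
    rows = []
    for gene, grp in table.groupby("gene", sort=True):
        sig = grp[(grp["adj_p"] < alpha) & (grp["avg_logfc"] != 0)]
        recs = sig.to_dict("records")
        for i in range(len(recs)):
            for j in range(i + 1, len(recs)):
                a, b = recs[i], recs[j]
                if np.sign(a["avg_logfc"]) != np.sign(b["avg_logfc"]):
                    row = {
                        "gene": gene,
                        "context_a": (a["cell_type"], a["region"], a["sex"]),
                        "context_b": (b["cell_type"], b["region"], b["sex"]),
                        "logfc_a": a["avg_logfc"],
                        "logfc_b": b["avg_logfc"],
                    }
                    if cell_classes is not None:
                        ca = cell_classes.get(a["cell_type"])
                        cb = cell_classes.get(b["cell_type"])
                        row["neuron_glia"] = (
                            ca is not None and cb is not None and ca != cb
                        )
                    rows.append(row)
    cols = ["gene", "context_a", "context_b", "logfc_a", "logfc_b"]
    if cell_classes is not None:
        cols.append("neuron_glia")
    return pd.DataFrame(rows, columns=cols)
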