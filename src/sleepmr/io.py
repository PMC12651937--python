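"""Reading and writing the package's file formats.

Everything is plain text: GWAS summary statistics as GWAS-SSF-like TSV,
LD matrices as square TSV with a SNP header, expression matrices as
genes x samples TSV, and result bundles as tidy TSV plus JSON summaries.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_gwas_summary",
    "write_gwas_summary",
    "read_ld_matrix",
    "write_ld_matrix",
    "read_expression",
    "write_expression",
    "file_sha256",
]

REQUIRED_COLUMNS = ["SNP", "A1", "A2", "BETA", "SE", "P"]
OPTIONAL_COLUMNS = ["CHR", "BP", "EAF", "N"]

_SYNONYMS = {
    "snp": "SNP",
    "rsid": "SNP",
    "variant_id": "SNP",
    "chr": "CHR",
    "chrom": "CHR",
    "chromosome": "CHR",
    "bp": "BP",
    "pos": "BP",
    "base_pair_location": "BP",
    "a1": "A1",
    "effect_allele": "A1",
    "a2": "A2",
    "other_allele": "A2",
    "eaf": "EAF",
    "effect_allele_frequency": "EAF",
    "beta": "BETA",
    "b": "BETA",
    "se": "SE",
    "standard_error": "SE",
    "p": "P",
    "pval": "P",
    "p_value": "P",
    "n": "N",
    "sample_size": "N",
}


def read_gwas_summary(path) -> pd.DataFrame:
    """Read a GWAS-SSF-like TSV into canonical columns.

    Column synonyms (beta/b, se/standard_error, p/pval, ...) are mapped to
    the canonical header.  Rows violating the record invariants (SE <= 0,
    P outside (0, 1], EAF outside [0, 1], identical alleles) are rejected
    and reported with their 1-based data line numbers via a ``rejected_rows``
    attribute on the returned frame.
    """
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str})
    rename = {c: _SYNONYMS.get(c.lower(), c.upper() if c.lower() in
                               {x.lower() for x in REQUIRED_COLUMNS + OPTIONAL_COLUMNS}
                               else c) for c in df.columns}
    df = df.rename(columns=rename)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")

    bad = pd.Series(False, index=df.index)
    reasons = {}

    def _flag(mask: pd.Series, reason: str) -> None:
        for i in df.index[mask & ~bad]:
            reasons[i] = reason
        bad.loc[mask] = True

    _flag(df["SE"] <= 0, "nonpositive SE")
    _flag((df["P"] <= 0) | (df["P"] > 1), "P outside (0, 1]")
    if "EAF" in df.columns:
        eaf = df["EAF"]
        _flag(eaf.notna() & ((eaf < 0) | (eaf > 1)), "EAF outside [0, 1]")
    _flag(
        df["A1"].astype(str).str.upper() == df["A2"].astype(str).str.upper(),
        "identical alleles",
    )

    rejected = [
        {"line": int(i) + 2, "reason": r} for i, r in sorted(reasons.items())
    ]  # +2: header line and 1-based numbering
    out = df.loc[~bad].reset_index(drop=True)
    out.attrs["rejected_rows"] = rejected
    return out


def write_gwas_summary(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_ld_matrix(ld: pd.DataFrame, path) -> None:
    ld.to_csv(path, sep="\t")


def read_ld_matrix(path) -> pd.DataFrame:
    ld = pd.read_csv(path, sep="\t", index_col=0)
    ld.columns = [str(c) for c in ld.columns]
    ld.index = [str(i) for i in ld.index]
    return ld


def write_expression(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene")


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_json(obj, path) -> None:
    """Deterministic JSON: sorted keys, no timestamps, numpy types coerced."""

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True, default=_default) + "\n"
    )
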