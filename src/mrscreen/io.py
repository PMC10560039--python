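"""Reading and writing of GWAS summary-statistics and LD tables.

The native layout is a GWAS-SSF-style tab-separated table with columns
``snp_id, chr, pos, effect_allele, other_allele, eaf, beta, se, pval, n``
(positions 1-based).  Foreign dialects are accommodated through a column
map; odds-ratio effect columns can be declared and are log-transformed at
ingestion so all downstream effects live on the beta / log-odds scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SSF_COLUMNS = [
    "snp_id",
    "chr",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]

LD_COLUMNS = ["snp_a", "snp_b", "r2"]

#: float format used by every writer; fixed so identical inputs give
#: byte-identical files.
FLOAT_FORMAT = "%.10g"


def write_table(df: pd.DataFrame, path) -> None:
    """Write any result table as a deterministic TSV."""
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def write_gwas(df: pd.DataFrame, path) -> None:
    """Write a GWAS summary-statistics table in the native SSF-style layout."""
    missing = [c for c in SSF_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"GWAS table is missing columns: {missing}")
    write_table(df[SSF_COLUMNS], path)


def read_gwas(path, column_map: dict | None = None, odds_ratio_col: str | None = None) -> pd.DataFrame:
    """Read a GWAS summary-statistics table.

    Parameters
    ----------
    path : str or path-like
        Tab-separated file.
    column_map : dict, optional
        Mapping from columns in the file to the native column names, for
        foreign dialects (e.g. ``{"rsid": "snp_id", "A1": "effect_allele"}``).
    odds_ratio_col : str, optional
        Name (after renaming) of a column holding odds ratios.  It is
        log-transformed into ``beta``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chr": str})
    if column_map:
        df = df.rename(columns=column_map)
    if odds_ratio_col is not None:
        df["beta"] = np.log(df[odds_ratio_col].astype(float))
    missing = [c for c in SSF_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"GWAS table {path!r} is missing columns: {missing}")
    df["chr"] = df["chr"].astype(str)
    return df


def write_ld(df: pd.DataFrame, path) -> None:
    write_table(df[LD_COLUMNS], path)


def read_ld(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in LD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"LD table {path!r} is missing columns: {missing}")
    return df


def ld_lookup(ld: pd.DataFrame | dict | None) -> dict:
    """Build a symmetric ``{(snp_a, snp_b): r2}`` lookup from an LD table.

    Missing pairs are treated as r2 = 0 by consumers.
    """
    if ld is None:
        return {}
    if isinstance(ld, dict):
        out = {}
        for (a, b), r2 in ld.items():
            out[(a, b)] = r2
            out[(b, a)] = r2
        return out
    out = {}
    for a, b, r2 in zip(ld["snp_a"], ld["snp_b"], ld["r2"]):
        out[(a, b)] = r2
        out[(b, a)] = r2
    return out
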