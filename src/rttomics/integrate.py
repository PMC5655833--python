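"""Gene-protein integration: matching, dual significance, correlation,
and annotation of previously reported Rett-syndrome hits.

Protein fold changes follow the signed convention (|FC| >= 1; -k means a
k-fold decrease) and are transformed to log2 before correlating with the
gene log2 fold changes, reconciling signed ratio tables with log2-scaled
fold-change axes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def signed_fold_to_log2(fc):
    """Signed fold change -> log2: fc >= 1 -> log2(fc); fc <= -1 -> -log2(-fc)."""
    arr = np.asarray(fc, dtype=float)
    if np.any(np.abs(arr) < 1):
        raise ValueError("signed fold changes must satisfy |fc| >= 1")
    out = np.where(arr >= 1, np.log2(np.abs(arr)), -np.log2(np.abs(arr)))
    if np.ndim(fc) == 0:
        return float(out[()])
    return out


def log2_to_signed_fold(value):
    """Inverse of :func:`signed_fold_to_log2`."""
    arr = np.asarray(value, dtype=float)
    out = np.where(arr >= 0, 2.0 ** arr, -(2.0 ** (-arr)))
    if np.ndim(value) == 0:
        return float(out[()])
    return out


def match_gene_protein(
    gene_table: pd.DataFrame,
    protein_table: pd.DataFrame,
    symbol_map: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pair detected genes with detected protein forms via gene symbols.

    ``symbol_map`` relates protein accessions to gene symbols (columns
    ``accession``, ``gene``); an accession mapping to more than one symbol
    raises with the conflicts listed. Matching is case-insensitive on the
    symbol, and each PTM form of a protein yields its own match. Returns
    ``(matches, unmatched_genes, unmatched_proteins)``.
    """
    sm = symbol_map.drop_duplicates(["accession", "gene"])
    conflicts = sm.groupby("accession")["gene"].nunique()
    conflicts = conflicts[conflicts > 1]
    if len(conflicts):
        raise ValueError(
            "ambiguous accession-to-symbol mapping for: "
            + ", ".join(sorted(conflicts.index))
        )
    acc_to_gene = sm.set_index("accession")["gene"].str.lower()

    genes = gene_table.rename(columns={
        "log2_fold_change": "gene_log2_fc",
        "p_value": "gene_p",
        "q_value": "gene_q",
    }).copy()
    for col in ("gene_p", "gene_q"):
        if col not in genes.columns:
            genes[col] = np.nan
    genes["_sym"] = genes["gene"].str.lower()

    prots = protein_table.rename(columns={
        "fold_change": "protein_fc",
        "p_value": "protein_p",
    }).copy()
    if "form" not in prots.columns:
        prots["form"] = "none"
    if "protein_p" not in prots.columns:
        prots["protein_p"] = np.nan
    prots["_sym"] = prots["accession"].map(acc_to_gene)

    merged = prots.merge(genes, on="_sym", how="inner")
    matches = merged[["gene", "accession", "form", "gene_log2_fc",
                      "gene_p", "gene_q", "protein_fc", "protein_p"]].copy()
    matches["protein_log2_fc"] = signed_fold_to_log2(
        matches["protein_fc"].to_numpy()
    )
    unmatched_genes = genes[~genes["_sym"].isin(prots["_sym"])] \
        .drop(columns="_sym").reset_index(drop=True)
    unmatched_proteins = prots[~prots["_sym"].isin(genes["_sym"])] \
        .drop(columns="_sym").reset_index(drop=True)
    return matches.reset_index(drop=True), unmatched_genes, unmatched_proteins


def significant_matches(
    matches: pd.DataFrame,
    gene_q: float = 0.05,
    protein_p: float = 0.1,
    relaxed: bool = False,
    relaxed_gene_p: float = 0.05,
) -> pd.DataFrame:
    """Matches where both sides are significant (strict inequalities).

    Default: gene q < 0.05 and protein p < 0.1. Relaxed mode substitutes
    gene p < 0.05 for the gene q threshold.
    """
    if relaxed:
        gene_ok = matches["gene_p"] < relaxed_gene_p
    else:
        gene_ok = matches["gene_q"] < gene_q
    return matches[gene_ok & (matches["protein_p"] < protein_p)] \
        .reset_index(drop=True)


def correlation(
    matches: pd.DataFrame,
    scale: str = "log2",
) -> tuple[float, int]:
    """Pearson correlation of gene vs protein fold change; returns (R, n).

    ``scale='log2'`` (default) correlates the gene log2 fold change with the
    protein signed fold change transformed to log2; ``scale='signed'``
    correlates against the raw signed ratio instead.
    """
    x = matches["gene_log2_fc"].to_numpy(dtype=float)
    y_col = "protein_log2_fc" if scale == "log2" else "protein_fc"
    if scale not in ("log2", "signed"):
        raise ValueError(f"unknown correlation scale {scale!r}")
    y = matches[y_col].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError(f"need >= 3 matches for a correlation, have {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one axis; correlation undefined")
    r = float(stats.pearsonr(x, y).statistic)
    return r, int(len(x))


def annotate_rtt_hits(
    matches: pd.DataFrame,
    citations: pd.DataFrame | dict,
) -> tuple[pd.DataFrame, dict]:
    """Tag matches previously reported as Rett-syndrome regulatory targets.

    ``citations`` maps gene symbols to citation labels (frame with columns
    ``gene`` and ``refs``, or a plain dict). Matches without a citation are
    tagged ``novel``. Returns the annotated matches and summary counts.
    """
    if isinstance(citations, dict):
        cite_map = {k.lower(): v for k, v in citations.items()}
    else:
        cite_map = {
            str(g).lower(): r
            for g, r in zip(citations["gene"], citations["refs"])
            if pd.notna(r) and str(r) != ""
        }
    out = matches.copy()
    out["rtt_refs"] = [
        cite_map.get(str(g).lower(), "novel") for g in out["gene"]
    ]
    n_known = int((out["rtt_refs"] != "novel").sum())
    counts = {"known": n_known, "novel": int(len(out) - n_known)}
    return out, counts
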