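"""Cuffdiff-style differential-expression table processing.

Loads gene-level DE tables (FPKM per group, log2 fold change, p, q,
locus coordinates, biotype), applies the study filters (removal of
significant putative non-coding genes, strict q < 0.05 significance with a
relaxed p < 0.05 mode), derives gene lengths from the locus, classifies
genes at the 100-kb short/long boundary and summarizes expression
directions.
"""

from __future__ import annotations

import logging
import re

import numpy as np
import pandas as pd

from .errors import SchemaError

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = [
    "gene", "locus", "value_1", "value_2",
    "log2_fold_change", "p_value", "q_value", "biotype",
]

_LOCUS_RE = re.compile(r"^(?P<chrom>[\w.]+):(?P<start>\d+)-(?P<end>\d+)$")

SHORT = "short"
LONG = "long"


def parse_locus(locus: str) -> tuple[str, int, int]:
    """Parse a Cuffdiff-style ``chrom:start-end`` locus string."""
    m = _LOCUS_RE.match(str(locus).strip())
    if not m:
        raise ValueError(f"malformed locus {locus!r}")
    return m["chrom"], int(m["start"]), int(m["end"])


def derive_locus_columns(table: pd.DataFrame) -> pd.DataFrame:
    """Add chrom/start/end and length_kb = (end - start) / 1000 from the locus."""
    parsed = [parse_locus(loc) for loc in table["locus"]]
    out = table.assign(
        chrom=[p[0] for p in parsed],
        start=[p[1] for p in parsed],
        end=[p[2] for p in parsed],
    )
    out["length_kb"] = (out["end"] - out["start"]) / 1000.0
    return out


def load_de_table(path) -> pd.DataFrame:
    """Load a gene DE table from TSV, rejecting malformed rows.

    Requires the columns {gene, locus, value_1, value_2, log2_fold_change,
    p_value, q_value, biotype}; a missing column raises ``SchemaError``
    naming it. Rows with an unparsable locus, end < start, or non-numeric
    statistics are dropped with their line numbers logged. Adds derived
    ``chrom``, ``start``, ``end`` and ``length_kb`` columns
    (length = (end - start) / 1000).
    """
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"DE table is missing required columns: {missing}")
    chroms, starts, ends = [], [], []
    bad_lines = []
    numeric = table[["value_1", "value_2", "log2_fold_change",
                     "p_value", "q_value"]].apply(pd.to_numeric, errors="coerce")
    for i, locus in enumerate(table["locus"]):
        line_no = i + 2  # 1-based, after the header line
        try:
            chrom, start, end = parse_locus(locus)
        except ValueError:
            bad_lines.append(line_no)
            chroms.append(None); starts.append(-1); ends.append(-1)
            continue
        if end < start:
            bad_lines.append(line_no)
        chroms.append(chrom); starts.append(start); ends.append(end)
    bad_numeric = numeric.isna().any(axis=1)
    for i in np.flatnonzero(bad_numeric.to_numpy()):
        bad_lines.append(i + 2)
    if bad_lines:
        logger.warning("rejected %d malformed DE rows at lines: %s",
                       len(set(bad_lines)), sorted(set(bad_lines)))
    table = table.assign(chrom=chroms, start=starts, end=ends)
    table[numeric.columns] = numeric
    keep = ~table.index.isin(
        [ln - 2 for ln in bad_lines]
    )
    table = table[keep].reset_index(drop=True)
    table["length_kb"] = (table["end"] - table["start"]) / 1000.0
    return table


def write_de_table(table: pd.DataFrame, path) -> None:
    table[REQUIRED_COLUMNS].to_csv(path, sep="\t", index=False,
                                   float_format="%.6g")


def filter_noncoding(table: pd.DataFrame, q_threshold: float = 0.05) -> pd.DataFrame:
    """Remove significant DE records mapping to putative non-coding genes.

    Only records that are both significant (q < ``q_threshold``) and
    non-protein-coding are removed; non-significant non-coding records are
    retained (the filter applies to the significant DE list only).
    """
    drop = (table["q_value"] < q_threshold) & \
        (table["biotype"] != "protein_coding")
    return table[~drop].reset_index(drop=True)


def significant_genes(
    table: pd.DataFrame,
    q_threshold: float = 0.05,
    relaxed: bool = False,
    relaxed_p: float = 0.05,
) -> pd.DataFrame:
    """Strictly significant genes: q < 0.05, or p < 0.05 in relaxed mode."""
    if relaxed:
        mask = table["p_value"] < relaxed_p
    else:
        mask = table["q_value"] < q_threshold
    return table[mask].reset_index(drop=True)


def gene_length_class(length_kb, boundary_kb: float = 100.0):
    """Classify genes as short (< boundary) or long (>= boundary).

    Genes exactly at the boundary are classed long (the boundary itself is
    a documented convention; the defining studies speak only of < 100 kb
    and > 100 kb).
    """
    arr = np.asarray(length_kb, dtype=float)
    out = np.where(arr < boundary_kb, SHORT, LONG)
    if np.ndim(length_kb) == 0:
        return str(out[()])
    return pd.Series(out, index=getattr(length_kb, "index", None))


def direction_summary(table_or_fc) -> dict:
    """Count increased (log2 FC > 0) / decreased (< 0) genes.

    Zero fold changes are counted separately, never in either direction.
    Percentages are over non-zero directions, rounded to the nearest
    integer for reporting; exact counts are retained.
    """
    if isinstance(table_or_fc, pd.DataFrame):
        fc = table_or_fc["log2_fold_change"]
    else:
        fc = pd.Series(table_or_fc)
    fc = fc.astype(float)
    n_inc = int((fc > 0).sum())
    n_dec = int((fc < 0).sum())
    n_zero = int((fc == 0).sum())
    denom = n_inc + n_dec
    return {
        "n_total": int(len(fc)),
        "n_increased": n_inc,
        "n_decreased": n_dec,
        "n_zero": n_zero,
        "pct_increased": int(round(100.0 * n_inc / denom)) if denom else 0,
        "pct_decreased": int(round(100.0 * n_dec / denom)) if denom else 0,
    }
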