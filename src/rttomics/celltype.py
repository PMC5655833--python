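"""CNS cell-type enrichment classification.

A gene is assigned to a cell type when its expression in a purified-cell
reference matrix is at least 3-fold that of every other cell type (ratio of
the top cell type to the maximum of the rest, boundary inclusive). The
three oligodendrocyte-lineage columns (precursors, newly formed,
myelinating) are collapsed into one oligodendrocyte column before
classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import FULL_CELL_TYPES, MERGED_CELL_TYPES, OLIGO_SUBTYPES

logger = logging.getLogger(__name__)

NOT_ENRICHED = "not_enriched"


def load_reference(path) -> pd.DataFrame:
    """Read a gene x cell-type reference TSV.

    Uses round-trip float parsing: the 3-fold rule is boundary inclusive, so
    a last-ulp parsing error on an exactly 3-fold-enriched gene would flip
    its call.
    """
    return pd.read_csv(path, sep="\t", index_col=0,
                       float_precision="round_trip")
ABSENT_FROM_REFERENCE = "absent_from_reference"
CALL_CATEGORIES = MERGED_CELL_TYPES + [NOT_ENRICHED, ABSENT_FROM_REFERENCE]


@dataclass(frozen=True)
class EnrichmentCall:
    """Cell-type call for one gene with its enrichment ratio (top / max of others)."""

    gene: str
    call: str
    ratio: float


def merge_oligo_subtypes(reference: pd.DataFrame, how: str = "max") -> pd.DataFrame:
    """Collapse the three oligodendrocyte-lineage columns into one.

    ``how='max'`` (default) takes the elementwise maximum, so a gene specific
    to any lineage stage counts as oligodendrocyte-enriched; ``how='mean'``
    averages the sub-columns. Other columns are untouched. The result has
    exactly the five merged cell types.
    """
    missing = [c for c in OLIGO_SUBTYPES if c not in reference.columns]
    if missing:
        raise ValueError(f"reference lacks oligodendrocyte sub-columns: {missing}")
    sub = reference[OLIGO_SUBTYPES]
    merged_col = sub.max(axis=1) if how == "max" else sub.mean(axis=1)
    if how not in ("max", "mean"):
        raise ValueError(f"unknown oligodendrocyte merge rule {how!r}")
    out = reference.drop(columns=OLIGO_SUBTYPES).copy()
    out["oligodendrocyte"] = merged_col
    return out[MERGED_CELL_TYPES]


def classify_cell_type(
    gene: str,
    merged_reference: pd.DataFrame,
    threshold: float = 3.0,
    compare: str = "max",
) -> EnrichmentCall:
    """Classify one gene by the 3-fold enrichment rule.

    The enrichment ratio is the top cell type's expression divided by the
    maximum (default) or mean of the remaining cell types; the gene is
    called for the top cell type iff ratio >= ``threshold`` (boundary
    inclusive). Genes absent from the reference get a distinct category;
    all-zero rows are not enriched (undefined ratio, logged); a zero
    denominator with positive numerator is enriched with an infinite ratio.
    """
    if gene not in merged_reference.index:
        return EnrichmentCall(gene, ABSENT_FROM_REFERENCE, float("nan"))
    row = merged_reference.loc[gene].astype(float)
    if (row < 0).any():
        raise ValueError(f"negative reference expression for gene {gene!r}")
    if float(row.max()) == 0.0:
        logger.warning("gene %s has an all-zero reference row", gene)
        return EnrichmentCall(gene, NOT_ENRICHED, float("nan"))
    top_type = row.idxmax()
    top = float(row[top_type])
    others = row.drop(top_type)
    denom = float(others.max()) if compare == "max" else float(others.mean())
    if denom == 0.0:
        return EnrichmentCall(gene, top_type, float("inf"))
    ratio = top / denom
    call = top_type if ratio >= threshold else NOT_ENRICHED
    return EnrichmentCall(gene, call, ratio)


def classify_genes(
    genes,
    merged_reference: pd.DataFrame,
    threshold: float = 3.0,
    compare: str = "max",
) -> pd.DataFrame:
    """Vectorized classification of many genes; one row per input gene."""
    ref = merged_reference.to_numpy(dtype=float)
    idx = merged_reference.index.get_indexer(pd.Index(genes))
    calls = np.full(len(idx), ABSENT_FROM_REFERENCE, dtype=object)
    ratios = np.full(len(idx), np.nan)
    present = idx >= 0
    if present.any():
        rows = ref[idx[present]]
        order = np.argsort(rows, axis=1)
        top_j = order[:, -1]
        top = rows[np.arange(len(rows)), top_j]
        if compare == "max":
            denom = rows[np.arange(len(rows)), order[:, -2]]
        else:
            denom = (rows.sum(axis=1) - top) / (rows.shape[1] - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(denom > 0, top / denom,
                         np.where(top > 0, np.inf, np.nan))
        names = merged_reference.columns.to_numpy()
        sub_calls = np.where(
            (top > 0) & (r >= threshold), names[top_j], NOT_ENRICHED
        ).astype(object)
        sub_calls[top == 0] = NOT_ENRICHED
        calls[present] = sub_calls
        ratios[present] = np.where(top > 0, r, np.nan)
    return pd.DataFrame({"gene": list(genes), "call": calls, "ratio": ratios})


def distribution_summary(calls: pd.DataFrame) -> dict:
    """Counts per call category plus fractions over classified genes.

    Fractions are over genes present in the reference (absent genes are
    counted but excluded from the denominator) and sum to 1.
    """
    counts = {c: int((calls["call"] == c).sum()) for c in CALL_CATEGORIES}
    classified = sum(v for c, v in counts.items()
                    if c != ABSENT_FROM_REFERENCE)
    fractions = {
        c: (counts[c] / classified if classified else 0.0)
        for c in CALL_CATEGORIES if c != ABSENT_FROM_REFERENCE
    }
    return {"counts": counts, "n_classified": classified,
            "fractions": fractions}
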