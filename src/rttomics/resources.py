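"""Packaged reference tables.

Two small published tables from the source study ship with the package:
the 35 significant DE genes previously reported as Rett-syndrome hits
(with the study's cortical log2 fold changes and prior-report citations),
and the 35 significant gene-protein matches (gene log2 fold change,
protein signed fold change, PTM form and prior-report citations).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _read(name: str) -> pd.DataFrame:
    with resources.files("rttomics.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def load_rtt_gene_hits() -> pd.DataFrame:
    """The 35 previously reported Rett-syndrome DE genes with log2 fold changes."""
    return _read("rtt_gene_hits.tsv")


def load_gene_protein_matches() -> pd.DataFrame:
    """The 35 significant gene-protein matches (signed protein fold changes)."""
    return _read("gene_protein_matches.tsv")
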