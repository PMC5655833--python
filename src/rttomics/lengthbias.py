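"""Gene-length x expression-direction cross-tabulation.

Cross-tabulates short/long gene class against increased/decreased
expression, overall and within each cell-type call stratum, keeping exact
integer counts so fractions such as 53/75 are reported from integers rather
than rounded percentages.
"""

from __future__ import annotations

import logging

import pandas as pd

from .celltype import ABSENT_FROM_REFERENCE, CALL_CATEGORIES
from .transcriptome import LONG, SHORT

logger = logging.getLogger(__name__)

OVERALL = "overall"
CELLS = ["short_increased", "short_decreased",
         "long_increased", "long_decreased", "zero_fc"]


def _tally(sub: pd.DataFrame) -> dict:
    fc = sub["log2_fold_change"].astype(float)
    length = sub["length_class"]
    return {
        "short_increased": int(((length == SHORT) & (fc > 0)).sum()),
        "short_decreased": int(((length == SHORT) & (fc < 0)).sum()),
        "long_increased": int(((length == LONG) & (fc > 0)).sum()),
        "long_decreased": int(((length == LONG) & (fc < 0)).sum()),
        "zero_fc": int((fc == 0).sum()),
        "n_genes": int(len(sub)),
    }


def crosstab_length_direction(
    genes: pd.DataFrame,
    calls: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Cross-tabulate length class against direction, overall and per stratum.

    ``genes`` needs ``gene``, ``log2_fold_change`` and ``length_class``
    columns; ``calls`` optionally supplies a cell-type ``call`` per gene
    (genes without one are tallied in the absent stratum, logged). Returns a
    frame indexed by stratum (``overall`` plus every call category) whose
    four direction x length cells sum to the stratum total (zero fold
    changes counted in their own column).
    """
    df = genes.copy()
    if calls is not None:
        call_map = calls.set_index("gene")["call"]
        df["call"] = df["gene"].map(call_map)
        n_missing = int(df["call"].isna().sum())
        if n_missing:
            logger.warning("%d genes lack a cell-type call; "
                           "counted as absent", n_missing)
        df["call"] = df["call"].fillna(ABSENT_FROM_REFERENCE)
    else:
        df["call"] = df.get("call", ABSENT_FROM_REFERENCE)

    rows = {OVERALL: _tally(df)}
    for cat in CALL_CATEGORIES:
        rows[cat] = _tally(df[df["call"] == cat])
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "stratum"
    return table


def direction_fractions(table: pd.DataFrame) -> pd.DataFrame:
    """Fractions with numerators/denominators retained as integer columns.

    For each stratum reports the increased fraction among long genes and
    among short genes (e.g. 53/75 long genes increased -> 0.7067).
    """
    out = pd.DataFrame(index=table.index)
    long_total = table["long_increased"] + table["long_decreased"]
    short_total = table["short_increased"] + table["short_decreased"]
    out["long_increased_n"] = table["long_increased"]
    out["long_total"] = long_total
    out["frac_long_increased"] = table["long_increased"] / long_total.where(long_total > 0)
    out["short_increased_n"] = table["short_increased"]
    out["short_total"] = short_total
    out["frac_short_increased"] = table["short_increased"] / short_total.where(short_total > 0)
    return out
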