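"""Cross-tabulate gene length class against expression direction.

Tallies short/long x increased/decreased counts overall and per cell-type
call stratum and reports the long-gene increased fraction (the quantity the
study highlights for the overall DE list and the neuronal stratum).
Writes results/length_direction.tsv.
"""

from pathlib import Path

import pandas as pd

from rttomics import lengthbias

ROOT = Path(__file__).resolve().parent.parent / "results"


def main():
    sig = pd.read_csv(ROOT / "significant_genes.tsv", sep="\t")
    calls = pd.read_csv(ROOT / "celltype_calls.tsv", sep="\t")
    table = lengthbias.crosstab_length_direction(sig, calls)
    table.to_csv(ROOT / "length_direction.tsv", sep="\t")
    fr = lengthbias.direction_fractions(table)
    print(table[["short_increased", "short_decreased",
                 "long_increased", "long_decreased", "n_genes"]])
    row = fr.loc["overall"]
    if row["long_total"] > 0:
        print(f"-> {int(row['long_increased_n'])}/{int(row['long_total'])} "
              f"long genes increased "
              f"({100 * row['frac_long_increased']:.0f}%)")


if __name__ == "__main__":
    main()
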