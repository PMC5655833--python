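"""Simulate every input the downstream analyses consume.

Generates (seed 1 throughout):
- an 8-run (4 wild-type vs 4 mutant) fragment-level DIA experiment over 100
  proteins, 20% carrying a true genotype effect, with RT-dependent drift and
  10% missingness, plus its ground-truth ledger;
- a 1000-gene Cuffdiff-style differential-expression table with cell-type
  enriched blocks and gene lengths spanning the 100-kb boundary;
- a purified-CNS-cell reference expression matrix whose designated genes are
  exactly 3-fold enriched.

Outputs under results/simulated/.
"""

from pathlib import Path

import pandas as pd

from rttomics import simulate, transcriptome

OUT = Path(__file__).resolve().parent.parent / "results" / "simulated"
SEED = 1


def main():
    OUT.mkdir(parents=True, exist_ok=True)

    dia_cfg = simulate.DiaSimConfig(n_proteins=100, frac_changed=0.2, seed=SEED)
    exp = simulate.simulate_dia_experiment(dia_cfg)
    simulate.write_dia_experiment(exp, OUT / "dia")
    print(f"DIA experiment: {len(exp.runs)} runs, "
          f"{len(exp.ledger.peptides)} peptides, "
          f"{len(exp.ledger.changed_proteins)} truly changed proteins")

    de_cfg = simulate.DeSimConfig(n_genes=1000, seed=SEED)
    table, truth = simulate.simulate_de_table(de_cfg)
    transcriptome.write_de_table(table, OUT / "de_table.tsv")
    truth.to_csv(OUT / "de_truth.tsv", sep="\t", index=False,
                 float_format="%.6g")
    print(f"DE table: {len(table)} genes, {int(truth['true_de'].sum())} truly "
          f"differential, {(truth['length_kb'] >= 100).sum()} genes >= 100 kb")

    assignments = dict(
        truth.loc[truth["cell_type"] != "none",
                  ["gene", "cell_type"]].itertuples(index=False, name=None))
    ref = simulate.simulate_celltype_reference(
        n_genes=1000, enriched_assignments=assignments,
        enrichment_factor=3.0, seed=SEED)
    extra = [g for g in table["gene"] if g not in assignments]
    ref = ref.rename(index=dict(zip(
        [g for g in ref.index if g.startswith("REFGENE")], extra)))
    # full precision: the 3-fold boundary is exact by construction and must
    # survive the round-trip through the TSV
    ref.to_csv(OUT / "celltype_reference.tsv", sep="\t")
    print(f"cell-type reference: {len(ref)} genes x {ref.shape[1]} cell types "
          f"({len(assignments)} designated enriched)")


if __name__ == "__main__":
    main()
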