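"""Synthetic-data generators with recorded ground truth.

Every input the pipeline consumes can be generated here: multi-run
fragment-level DIA trace tables with retention-time-dependent multiplicative
matrix effects, missingness and genotype effects on a known protein subset;
Cuffdiff-style differential-expression gene tables with cell-type-enriched
blocks and gene lengths spanning the 100-kb boundary; and a purified-CNS-cell
reference expression matrix with the three oligodendrocyte-lineage
sub-columns. Fixed seeds give bit-identical outputs, and each generator
operation draws from its own PRNG stream (seeded from the config seed plus
an operation tag) so adding operations does not perturb existing fixtures.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError

CONTROL = "control"
MUTANT = "mutant"

FULL_CELL_TYPES = [
    "neuron", "astrocyte", "microglia",
    "opc", "newly_formed_oligodendrocyte", "myelinating_oligodendrocyte",
    "endothelial",
]
MERGED_CELL_TYPES = ["neuron", "astrocyte", "microglia", "oligodendrocyte",
                     "endothelial"]
OLIGO_SUBTYPES = ["opc", "newly_formed_oligodendrocyte",
                  "myelinating_oligodendrocyte"]


def _rng(seed: int, tag: str) -> np.random.Generator:
    """One PRNG stream per generator operation: seed + CRC32(tag)."""
    return np.random.default_rng([int(seed), zlib.crc32(tag.encode())])


# ---------------------------------------------------------------------------
# DIA experiment simulation
# ---------------------------------------------------------------------------

@dataclass
class DiaSimConfig:
    """Study-design parameters for a simulated DIA experiment.

    Defaults emulate the study design: 4 biological replicates per genotype,
    a 90-minute gradient, smooth per-run multiplicative matrix effects as a
    cubic function of retention time, and log-normal peptide abundances with
    Dirichlet-partitioned fragment intensities.
    """

    n_proteins: int = 100
    peptides_per_protein: tuple[int, int] = (2, 6)
    n_runs_per_group: int = 4
    frac_changed: float = 0.2
    effect_log2: tuple[float, float] = (0.5, 1.5)
    rt_range: tuple[float, float] = (10.0, 90.0)
    drift_scale: float = 0.3
    fragment_count_range: tuple[int, int] = (6, 12)
    missing_rate: float = 0.1
    noise_cv: float = 0.1
    rt_shift_sd_minutes: float = 1.0
    rt_slope_sd: float = 0.005
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 0:
            raise ConfigError("n_proteins must be >= 0")
        if self.n_runs_per_group < 2:
            raise ConfigError("n_runs_per_group must be >= 2")
        for name in ("frac_changed", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        lo, hi = self.peptides_per_protein
        if lo < 1 or hi < lo:
            raise ConfigError("peptides_per_protein must be a range with min >= 1")
        lo, hi = self.fragment_count_range
        if lo < 1 or hi < lo:
            raise ConfigError("fragment_count_range must be a range with min >= 1")
        if self.rt_range[1] <= self.rt_range[0]:
            raise ConfigError("rt_range must be increasing")
        if self.effect_log2[0] < 0 or self.effect_log2[1] < self.effect_log2[0]:
            raise ConfigError("effect_log2 bounds must be 0 <= low <= high")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be >= 0")
        if self.drift_scale < 0:
            raise ConfigError("drift_scale must be >= 0")


@dataclass
class GroundTruthLedger:
    """Planted truth for a simulated DIA experiment.

    ``proteins``: one row per protein with its true log2 fold change
    (0 for unchanged proteins) and a ``changed`` flag.
    ``peptides``: peptide -> protein assignment, base abundance, canonical
    retention time.
    ``true_abundance``: peptide x run abundances before drift and noise
    (genotype effect included for mutant runs).
    ``drift_coefficients``: per-run cubic polynomial coefficients of the
    multiplicative log-drift.
    ``rt_transforms``: per-run (slope, shift) distortion of retention time.
    """

    proteins: pd.DataFrame
    peptides: pd.DataFrame
    true_abundance: pd.DataFrame
    drift_coefficients: dict[str, np.ndarray]
    rt_transforms: dict[str, tuple[float, float]]

    @property
    def changed_proteins(self) -> set[str]:
        return set(self.proteins.loc[self.proteins["changed"], "protein_acc"])


@dataclass
class DiaExperiment:
    """Simulated experiment bundle: traces, detections, groups, truth."""

    traces: pd.DataFrame
    detections: pd.DataFrame
    groups: dict[str, str]
    ledger: GroundTruthLedger

    @property
    def runs(self) -> list[str]:
        return list(self.detections.columns)


def drift_factor(coeffs: np.ndarray, rt: np.ndarray,
                 rt_range: tuple[float, float]) -> np.ndarray:
    """Multiplicative RT-dependent matrix effect: exp(cubic in scaled RT)."""
    x = (np.asarray(rt, dtype=float) - rt_range[0]) / (rt_range[1] - rt_range[0])
    log_f = coeffs[0] + coeffs[1] * x + coeffs[2] * x ** 2 + coeffs[3] * x ** 3
    return np.exp(log_f)


N_SCANS = 9
SCAN_CYCLE_MIN = 0.1
PEAK_SIGMA_MIN = 0.18


def simulate_dia_experiment(config: DiaSimConfig) -> DiaExperiment:
    """Simulate fragment-level DIA traces for a two-genotype comparison.

    Every peptide elutes as a Gaussian peak sampled at 9 MS/MS scans
    (0.1-minute cycle); fragment intensities partition the peptide abundance
    by a Dirichlet draw; per-run matrix effects multiply intensities by a
    smooth cubic function of retention time; multiplicative log-normal noise
    with coefficient of variation ``noise_cv`` is applied per fragment and
    scan. Missingness removes a peptide from a run's identification list
    (independently per peptide x run) but its signal remains in the trace
    table, so cross-run extraction can recover it.
    """
    config.validate()
    seed = config.seed
    n_prot = config.n_proteins
    R = 2 * config.n_runs_per_group
    runs = [f"ctrl_{i + 1}" for i in range(config.n_runs_per_group)] + \
           [f"mut_{i + 1}" for i in range(config.n_runs_per_group)]
    groups = {r: (CONTROL if r.startswith("ctrl") else MUTANT) for r in runs}

    # --- proteins and planted effects -------------------------------------
    rng_fx = _rng(seed, "dia/effects")
    accs = [f"SIM{i:04d}" for i in range(n_prot)]
    n_changed = int(round(config.frac_changed * n_prot))
    changed_idx = rng_fx.choice(n_prot, size=n_changed, replace=False) \
        if n_changed else np.array([], dtype=int)
    true_log2 = np.zeros(n_prot)
    if n_changed:
        lo, hi = config.effect_log2
        mag = rng_fx.uniform(lo, hi, size=n_changed) if hi > lo \
            else np.full(n_changed, lo)
        sign = rng_fx.choice([-1.0, 1.0], size=n_changed)
        true_log2[changed_idx] = sign * mag
    proteins = pd.DataFrame({
        "protein_acc": accs,
        "true_log2_fc": true_log2,
        "changed": np.isin(np.arange(n_prot), changed_idx),
    })

    # --- peptides ---------------------------------------------------------
    rng_pep = _rng(seed, "dia/peptides")
    lo, hi = config.peptides_per_protein
    n_pep_per = rng_pep.integers(lo, hi + 1, size=n_prot)
    pep_protein = np.repeat(np.arange(n_prot), n_pep_per)
    n_pep = len(pep_protein)
    pep_ids = [f"PEP{j:05d}" for j in range(n_pep)]
    base = rng_pep.lognormal(mean=np.log(1e5), sigma=1.0, size=n_pep)
    pep_rt = rng_pep.uniform(*config.rt_range, size=n_pep)
    peptides = pd.DataFrame({
        "peptide_id": pep_ids,
        "protein_acc": [accs[i] for i in pep_protein],
        "modification": "none",
        "base_abundance": base,
        "rt_minutes": pep_rt,
    })

    # true per-run abundance (before drift and noise)
    fc = 2.0 ** true_log2[pep_protein]
    abund = np.tile(base[:, None], (1, R)).astype(float)
    for j, r in enumerate(runs):
        if groups[r] == MUTANT:
            abund[:, j] = base * fc
    true_abundance = pd.DataFrame(abund, index=pep_ids, columns=runs)

    # --- per-run drift and RT distortion ----------------------------------
    rng_run = _rng(seed, "dia/runs")
    drift = {r: rng_run.normal(0.0, config.drift_scale, size=4) for r in runs}
    rt_tf = {
        r: (1.0 + rng_run.normal(0.0, config.rt_slope_sd),
            rng_run.normal(0.0, config.rt_shift_sd_minutes))
        for r in runs
    }

    # --- fragments --------------------------------------------------------
    rng_frag = _rng(seed, "dia/fragments")
    flo, fhi = config.fragment_count_range
    n_frag_per = rng_frag.integers(flo, fhi + 1, size=n_pep)
    frag_pep = np.repeat(np.arange(n_pep), n_frag_per)
    n_frag = len(frag_pep)
    shares = np.concatenate([
        rng_frag.dirichlet(np.full(k, 2.0)) for k in n_frag_per
    ])
    ion_type = rng_frag.choice(["b", "y", "a"], size=n_frag, p=[0.45, 0.45, 0.10])
    charge = rng_frag.choice([1, 2, 3], size=n_frag, p=[0.5, 0.4, 0.1])
    frag_mz = np.round(rng_frag.uniform(200.0, 1500.0, size=n_frag), 4)
    frag_ids = np.array([f"F{j:07d}" for j in range(n_frag)])

    # --- missingness -------------------------------------------------------
    rng_mis = _rng(seed, "dia/missingness")
    detected = rng_mis.random((n_pep, R)) >= config.missing_rate
    detections = pd.DataFrame(detected, index=pep_ids, columns=runs)

    # --- trace rows (vectorized over fragment x run x scan) ---------------
    rng_noise = _rng(seed, "dia/noise")
    sigma = float(np.sqrt(np.log1p(config.noise_cv ** 2)))
    scan_offsets = (np.arange(N_SCANS) - (N_SCANS - 1) / 2) * SCAN_CYCLE_MIN
    shape = np.exp(-(scan_offsets ** 2) / (2 * PEAK_SIGMA_MIN ** 2))

    frames = []
    for j, r in enumerate(runs):
        slope, shift = rt_tf[r]
        apex_rt = pep_rt * slope + shift            # per peptide, this run
        rt = apex_rt[frag_pep][:, None] + scan_offsets[None, :]
        inten = (
            abund[frag_pep, j][:, None]
            * shares[:, None]
            * shape[None, :]
            * drift_factor(drift[r], rt.ravel(), config.rt_range).reshape(rt.shape)
        )
        if sigma > 0:
            inten = inten * np.exp(
                rng_noise.normal(0.0, sigma, size=inten.shape) - sigma ** 2 / 2
            )
        frames.append(pd.DataFrame({
            "run_id": r,
            "peptide_id": np.repeat(np.array(pep_ids)[frag_pep], N_SCANS),
            "protein_acc": np.repeat(
                np.array(accs)[pep_protein[frag_pep]], N_SCANS),
            "modification": "none",
            "fragment_id": np.repeat(frag_ids, N_SCANS),
            "ion_type": np.repeat(ion_type, N_SCANS),
            "charge": np.repeat(charge, N_SCANS),
            "mz": np.repeat(frag_mz, N_SCANS),
            "rt_minutes": rt.ravel(),
            "scan_index": np.tile(np.arange(N_SCANS), n_frag),
            "intensity": inten.ravel(),
        }))
    traces = pd.concat(frames, ignore_index=True)

    ledger = GroundTruthLedger(proteins, peptides, true_abundance, drift, rt_tf)
    return DiaExperiment(traces, detections, groups, ledger)


def write_dia_experiment(exp: DiaExperiment, outdir: str | Path) -> None:
    """Write trace TSVs (one per run), a detections TSV and the ledger."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for run, sub in exp.traces.groupby("run_id"):
        sub.to_csv(outdir / f"traces_{run}.tsv", sep="\t", index=False,
                   float_format="%.6g")
    exp.detections.to_csv(outdir / "detections.tsv", sep="\t")
    exp.ledger.proteins.to_csv(outdir / "truth_proteins.tsv", sep="\t",
                               index=False, float_format="%.6g")
    exp.ledger.peptides.to_csv(outdir / "truth_peptides.tsv", sep="\t",
                               index=False, float_format="%.6g")
    exp.ledger.true_abundance.to_csv(outdir / "truth_abundance.tsv", sep="\t",
                                     float_format="%.6g")
    meta = {
        "groups": exp.groups,
        "drift_coefficients": {r: list(map(float, c))
                               for r, c in exp.ledger.drift_coefficients.items()},
        "rt_transforms": {r: [float(a), float(b)]
                          for r, (a, b) in exp.ledger.rt_transforms.items()},
    }
    (outdir / "truth_meta.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n"
    )


# ---------------------------------------------------------------------------
# Differential-expression gene table simulation
# ---------------------------------------------------------------------------

@dataclass
class DeSimConfig:
    """Design for a simulated Cuffdiff-style gene differential-expression table.

    Gene lengths are log-normal around a ~30-kb median so the population
    spans the 100-kb short/long boundary; direction biases default to the
    short/long split observed in the study cortex (about a quarter of short
    DE genes and about 71% of long DE genes increased).
    """

    n_genes: int = 1000
    enriched_blocks: dict[str, int] = field(default_factory=lambda: {
        "neuron": 60, "astrocyte": 50, "microglia": 20,
        "oligodendrocyte": 40, "endothelial": 20,
    })
    frac_de: float = 0.1
    effect_log2: tuple[float, float] = (0.5, 2.0)
    up_prob_short: float = 0.25
    up_prob_long: float = 0.71
    length_log_median_kb: float = 30.0
    length_log_sigma: float = 1.2
    frac_noncoding: float = 0.05
    n_replicates: int = 4
    dispersion: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 0:
            raise ConfigError("n_genes must be >= 0")
        if sum(self.enriched_blocks.values()) > self.n_genes:
            raise ConfigError("enriched_blocks sizes exceed n_genes")
        unknown = set(self.enriched_blocks) - set(MERGED_CELL_TYPES)
        if unknown:
            raise ConfigError(f"enriched_blocks has unknown cell types {unknown}")
        for name in ("frac_de", "up_prob_short", "up_prob_long",
                     "frac_noncoding"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.n_replicates < 2:
            raise ConfigError("n_replicates must be >= 2")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be positive")
        if self.length_log_median_kb <= 0 or self.length_log_sigma <= 0:
            raise ConfigError("gene length distribution parameters must be positive")


CHROMOSOMES = [f"chr{i}" for i in range(1, 20)] + ["chrX"]


def simulate_de_table(config: DeSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a gene DE table plus per-gene truth labels.

    Replicate log2 FPKM values are drawn per genotype group with standard
    deviation ``dispersion``; the per-gene p-value is a Welch t-test over
    replicates and q-values are Benjamini-Hochberg over all genes.
    Coordinates are consistent with the assigned lengths, and a fraction of
    genes carry non-coding biotypes.

    Returns ``(table, truth)`` where ``table`` has the Cuffdiff-style columns
    ``gene, locus, value_1, value_2, log2_fold_change, p_value, q_value,
    biotype`` and ``truth`` records ``true_de, true_log2_fc, cell_type,
    length_kb`` per gene.
    """
    config.validate()
    n = config.n_genes
    rng = _rng(config.seed, "de/table")
    genes = [f"GENE{i:05d}" for i in range(n)]

    cell_type = np.array(["none"] * n, dtype=object)
    pos = 0
    for ct in MERGED_CELL_TYPES:
        k = config.enriched_blocks.get(ct, 0)
        cell_type[pos:pos + k] = ct
        pos += k

    lengths_kb = rng.lognormal(
        mean=np.log(config.length_log_median_kb),
        sigma=config.length_log_sigma, size=n,
    )
    is_long = lengths_kb >= 100.0

    n_de = int(round(config.frac_de * n))
    de_idx = rng.choice(n, size=n_de, replace=False) if n_de else \
        np.array([], dtype=int)
    true_de = np.isin(np.arange(n), de_idx)
    lo, hi = config.effect_log2
    mag = rng.uniform(lo, hi, size=n)
    up_prob = np.where(is_long, config.up_prob_long, config.up_prob_short)
    sign = np.where(rng.random(n) < up_prob, 1.0, -1.0)
    true_log2 = np.where(true_de, sign * mag, 0.0)

    base_log2_fpkm = rng.normal(4.0, 1.5, size=n)
    reps = config.n_replicates
    rep1 = base_log2_fpkm[:, None] + rng.normal(0, config.dispersion, (n, reps))
    rep2 = (base_log2_fpkm + true_log2)[:, None] + \
        rng.normal(0, config.dispersion, (n, reps))
    t_res = stats.ttest_ind(rep2, rep1, axis=1, equal_var=False)
    pvals = np.asarray(t_res.pvalue)
    qvals = multipletests(pvals, method="fdr_bh")[1]

    value_1 = 2.0 ** rep1.mean(axis=1)
    value_2 = 2.0 ** rep2.mean(axis=1)
    log2_fc = np.log2(value_2 / value_1)

    chrom = rng.choice(CHROMOSOMES, size=n)
    start = rng.integers(1, 150_000_000, size=n)
    end = start + np.round(lengths_kb * 1000).astype(np.int64)
    locus = [f"{c}:{s}-{e}" for c, s, e in zip(chrom, start, end)]
    biotype = np.array(["protein_coding"] * n, dtype=object)
    n_nc = int(round(config.frac_noncoding * n))
    if config.frac_noncoding > 0 and n > 0:
        n_nc = max(1, n_nc)
    if n_nc:
        nc_idx = rng.choice(n, size=n_nc, replace=False)
        biotype[nc_idx] = rng.choice(
            ["lincRNA", "antisense", "processed_pseudogene"], size=n_nc)

    table = pd.DataFrame({
        "gene": genes,
        "locus": locus,
        "value_1": value_1,
        "value_2": value_2,
        "log2_fold_change": log2_fc,
        "p_value": pvals,
        "q_value": qvals,
        "biotype": biotype,
    })
    truth = pd.DataFrame({
        "gene": genes,
        "true_de": true_de,
        "true_log2_fc": true_log2,
        "cell_type": cell_type,
        "length_kb": np.round(lengths_kb * 1000).astype(np.int64) / 1000.0,
    })
    return table, truth


# ---------------------------------------------------------------------------
# Cell-type reference matrix simulation
# ---------------------------------------------------------------------------

def simulate_celltype_reference(
    n_genes: int,
    enriched_assignments: dict[str, str] | None = None,
    enrichment_factor: float = 3.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a gene x cell-type reference expression matrix.

    ``enriched_assignments`` maps gene symbols to a merged cell-type label;
    each designated gene's expression in the target cell type equals
    ``enrichment_factor`` times the maximum over all other cell types (for
    oligodendrocyte assignments the enriched value goes into one of the
    three lineage sub-columns). All other genes are constructed so that no
    cell type exceeds the others 3-fold in the merged view. Returns a frame
    indexed by gene with the seven full cell-type columns.
    """
    if enrichment_factor <= 0:
        raise ConfigError("enrichment_factor must be positive")
    enriched_assignments = enriched_assignments or {}
    for gene, ct in enriched_assignments.items():
        if ct not in MERGED_CELL_TYPES:
            raise ConfigError(f"unknown cell-type label {ct!r} for gene {gene!r}")
    rng = _rng(seed, "celltype/reference")

    assigned = list(enriched_assignments)
    n_extra = max(0, n_genes - len(assigned))
    gene_names = assigned + [f"REFGENE{i:05d}" for i in range(n_extra)]
    gene_names = gene_names[:max(n_genes, len(assigned))]

    rows = []
    for gene in gene_names:
        expr = {c: 0.0 for c in FULL_CELL_TYPES}
        target = enriched_assignments.get(gene)
        base = rng.uniform(1.0, 10.0, size=len(MERGED_CELL_TYPES))
        if target is None:
            # cap the top merged value strictly below 3x the runner-up
            order = np.argsort(base)
            runner_up = base[order[-2]]
            top_cap = runner_up * rng.uniform(1.0, 2.9)
            base[order[-1]] = min(base[order[-1]], top_cap)
            for ct, v in zip(MERGED_CELL_TYPES, base):
                if ct == "oligodendrocyte":
                    split = rng.dirichlet(np.ones(3))
                    for sub, s in zip(OLIGO_SUBTYPES, split):
                        expr[sub] = v * s
                    # the merged view takes the max of the sub-columns, so
                    # pin the largest sub-column at the merged value
                    expr[OLIGO_SUBTYPES[int(np.argmax(split))]] = v
                else:
                    expr[ct] = v
        else:
            others = [c for c in MERGED_CELL_TYPES if c != target]
            vals = rng.uniform(1.0, 10.0, size=len(others))
            for ct, v in zip(others, vals):
                if ct == "oligodendrocyte":
                    expr[rng.choice(OLIGO_SUBTYPES)] = v
                else:
                    expr[ct] = v
            m = float(vals.max())
            peak = enrichment_factor * m
            # guarantee peak / m >= factor after float rounding so the
            # boundary-inclusive classifier sees exactly the designed ratio
            while peak / m < enrichment_factor:
                peak = np.nextafter(peak, np.inf)
            if target == "oligodendrocyte":
                expr[rng.choice(OLIGO_SUBTYPES)] = peak
            else:
                expr[target] = peak
        rows.append(expr)
    ref = pd.DataFrame(rows, index=pd.Index(gene_names, name="gene"),
                       columns=FULL_CELL_TYPES, dtype=float)
    return ref
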