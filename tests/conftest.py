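import numpy as np
import pandas as pd
import pytest

from rttomics import dia, simulate


@pytest.fixture(scope="session")
def tiny_experiment():
    """A small simulated DIA experiment reused across quantification tests."""
    cfg = simulate.DiaSimConfig(
        n_proteins=15, peptides_per_protein=(2, 4), frac_changed=0.2,
        missing_rate=0.1, seed=3,
    )
    return simulate.simulate_dia_experiment(cfg)


@pytest.fixture(scope="session")
def tiny_quant(tiny_experiment):
    exp = tiny_experiment
    matrix, quants = dia.quantify_experiment(exp.traces, exp.detections, exp.groups)
    return matrix, quants


def make_trace(frag_specs, scans=None):
    """Build a one-peptide trace frame from (mz, ion, charge, [intensities])."""
    scans = scans if scans is not None else None
    rows = []
    for fid, (mz, ion, charge, intensities) in enumerate(frag_specs):
        for s, inten in enumerate(intensities):
            rows.append({
                "run_id": "run_1", "peptide_id": "PEP", "protein_acc": "P1",
                "modification": "none", "fragment_id": f"F{fid}",
                "ion_type": ion, "charge": charge, "mz": mz,
                "rt_minutes": 10.0 + 0.1 * s, "scan_index": s,
                "intensity": float(inten),
            })
    return pd.DataFrame(rows)


@pytest.fixture
def simple_matrix():
    """A fully measured 3-peptide x 4-run abundance matrix."""
    runs = ["ctrl_1", "ctrl_2", "mut_1", "mut_2"]
    peps = ["PEP0", "PEP1", "PEP2"]
    values = pd.DataFrame(
        [[10.0, 12.0, 20.0, 22.0],
         [5.0, 6.0, 10.0, 11.0],
         [100.0, 90.0, 95.0, 105.0]],
        index=peps, columns=runs,
    )
    status = pd.DataFrame(dia.MEASURED, index=peps, columns=runs)
    apex = pd.DataFrame(
        np.tile([[20.0], [40.0], [60.0]], (1, 4)), index=peps, columns=runs
    )
    return dia.PeptideAbundanceMatrix(values, status, apex)
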