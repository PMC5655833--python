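"""Unit tests for the DIA quantification engine."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from rttomics import dia
from tests.conftest import make_trace


# ---------------------------------------------------------------------------
# inclusion lists
# ---------------------------------------------------------------------------

class TestInclusionList:
    @pytest.mark.parametrize("start,end,step,width,expected", [
        (501.0, 552.0, 1.5, 2.5, 35),    # the study's first precursor range
        (501.0, 501.0, 1.5, 2.5, 1),
        (553.5, 604.5, 1.5, 2.5, 35),    # floor((604.5-553.5)/1.5)+1
    ])
    def test_center_counts(self, start, end, step, width, expected):
        lst = dia.build_inclusion_list(start, end, step, width)
        assert len(lst) == expected
        assert np.allclose(np.diff(lst.centers), step)

    def test_window_overlap(self):
        lst = dia.build_inclusion_list(501.0, 552.0, 1.5, 2.5)
        windows = lst.windows
        overlaps = windows[:-1, 1] - windows[1:, 0]
        assert np.allclose(overlaps, 1.0)
        assert lst.overlap == pytest.approx(1.0)

    def test_gap_warning_and_errors(self):
        with pytest.warns(UserWarning, match="gaps"):
            dia.build_inclusion_list(500.0, 510.0, step=3.0, isolation_width=2.5)
        with pytest.raises(ValueError):
            dia.build_inclusion_list(-1.0, 10.0)
        with pytest.raises(ValueError):
            dia.build_inclusion_list(510.0, 500.0)
        with pytest.raises(ValueError):
            dia.build_inclusion_list(500.0, 510.0, step=0.0)


# ---------------------------------------------------------------------------
# deconvolution
# ---------------------------------------------------------------------------

class TestDeconvolution:
    def test_apex_consistent_fragment_retained(self):
        trace = make_trace([(500.0, "y", 1, [10, 100, 95])])
        res = dia.deconvolve_fragments(trace)
        assert res.apex_scan == 1
        assert res.fragments["fragment_mz"].nunique() == 1

    def test_apex_inconsistent_fragment_dropped(self):
        # fragment B peaks away from the peptide apex: 60 < 0.7 * 100
        trace = make_trace([
            (500.0, "y", 1, [10, 1000, 900]),   # defines the apex (scan 1)
            (600.0, "b", 1, [100, 60, 20]),
        ])
        res = dia.deconvolve_fragments(trace)
        assert 600.0 not in set(res.fragments["fragment_mz"])
        assert 500.0 in set(res.fragments["fragment_mz"])

    def test_mz_within_tolerance_merged(self):
        trace = make_trace([
            (500.003, "y", 1, [5, 50, 40]),
            (500.010, "y", 1, [5, 50, 40]),   # delta 0.007 <= 0.01
        ])
        res = dia.deconvolve_fragments(trace)
        assert res.fragments["fragment_group"].nunique() == 1
        apex_row = res.fragments[res.fragments["scan_index"] == res.apex_scan]
        assert apex_row["intensity"].iloc[0] == pytest.approx(100.0)

    def test_all_zero_trace_empty_set(self):
        trace = make_trace([(500.0, "y", 1, [0, 0, 0])])
        res = dia.deconvolve_fragments(trace)
        assert res.fragments.empty
        assert res.apex_scan is None

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(200, 1500), min_size=1, max_size=30))
    def test_mz_grouping_respects_tolerance(self, mzs):
        labels = dia.group_fragment_mz(np.array(mzs), tolerance=0.01)
        arr = np.array(mzs)
        for g in np.unique(labels):
            vals = np.sort(arr[labels == g])
            assert vals[-1] - vals[0] <= 0.01 + 1e-12 or len(vals) == 1 or \
                np.all(np.diff(vals) <= 0.01 + 1e-12)
        # distinct groups are separated at their anchors
        assert labels.max() + 1 == len(set(labels))


# ---------------------------------------------------------------------------
# fragment selection
# ---------------------------------------------------------------------------

def frag_summary(rows):
    return pd.DataFrame(rows, columns=["fragment_mz", "ion_type", "charge",
                                       "intensity"])


class TestFragmentSelection:
    def test_caps_at_nine_most_intense(self):
        rows = [(200.0 + i, "y", 1, 100.0 - i) for i in range(12)]
        sel = dia.select_quant_fragments(frag_summary(rows))
        assert len(sel) == 9
        assert sel["intensity"].min() == pytest.approx(100.0 - 8)

    def test_fewer_than_five_unquantifiable(self):
        rows = [(200.0 + i, "y", 1, 100.0) for i in range(4)]
        assert dia.select_quant_fragments(frag_summary(rows)) is None

    def test_low_intensity_and_wrong_ions_excluded(self):
        rows = [(200.0, "y", 1, 100.0),
                (201.0, "y", 1, 9.0),     # 9% of base peak: ineligible
                (202.0, "a", 1, 90.0),    # not a b/y ion
                (203.0, "y", 3, 90.0),    # charge 3+
                (204.0, "b", 2, 50.0),
                (205.0, "b", 1, 40.0),
                (206.0, "y", 2, 30.0),
                (207.0, "y", 1, 20.0)]
        sel = dia.select_quant_fragments(frag_summary(rows))
        assert sel is not None
        assert set(sel["fragment_mz"]) == {200.0, 204.0, 205.0, 206.0, 207.0}


# ---------------------------------------------------------------------------
# AUC integration
# ---------------------------------------------------------------------------

class TestAuc:
    def test_rectangle(self):
        df = pd.DataFrame({
            "fragment_group": 0,
            "rt_minutes": [0.0, 1.0, 2.0],
            "intensity": [10.0, 10.0, 10.0],
        })
        assert dia.integrate_ms2_auc(df) == pytest.approx(20.0)

    def test_additive_over_fragments(self):
        df = pd.DataFrame({
            "fragment_group": [0, 0, 1, 1],
            "rt_minutes": [0.0, 2.0, 0.0, 1.0],
            "intensity": [10.0, 10.0, 5.0, 5.0],
        })
        assert dia.integrate_ms2_auc(df) == pytest.approx(20.0 + 5.0)

    def test_triangle(self):
        df = pd.DataFrame({
            "fragment_group": 0,
            "rt_minutes": [0.0, 1.0, 2.0],
            "intensity": [0.0, 10.0, 0.0],
        })
        assert dia.integrate_ms2_auc(df) == pytest.approx(10.0)

    def test_single_point_contributes_zero(self):
        df = pd.DataFrame({
            "fragment_group": [0, 1, 1],
            "rt_minutes": [1.0, 0.0, 2.0],
            "intensity": [999.0, 3.0, 3.0],
        })
        assert dia.integrate_ms2_auc(df) == pytest.approx(6.0)

    def test_empty_window_is_zero(self):
        df = pd.DataFrame({
            "fragment_group": [0], "rt_minutes": [5.0], "intensity": [10.0],
        })
        assert dia.integrate_ms2_auc(df, rt_window=(20.0, 21.0)) == 0.0


# ---------------------------------------------------------------------------
# RT mapping
# ---------------------------------------------------------------------------

class TestRtMap:
    def test_identity(self):
        rt = pd.Series([10.0, 20, 30, 40, 50], index=list("abcde"))
        m = dia.fit_rt_map(rt, rt)
        assert m.slope == pytest.approx(1.0)
        assert m.intercept == pytest.approx(0.0, abs=1e-9)
        assert m.residual_scale == pytest.approx(0.0, abs=1e-9)

    def test_constant_shift(self):
        rt = pd.Series([10.0, 20, 30, 40, 50], index=list("abcde"))
        m = dia.fit_rt_map(rt, rt + 2.0)
        assert m.slope == pytest.approx(1.0)
        assert m.intercept == pytest.approx(2.0)

    def test_noisy_affine_matches_closed_form(self):
        rng = np.random.default_rng(0)
        x = pd.Series(rng.uniform(10, 90, 40))
        y = 1.02 * x + 1.5 + rng.normal(0, 0.05, 40)
        m = dia.fit_rt_map(x, y)
        # closed-form least squares: slope = cov(x,y)/var(x)
        slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        intercept = y.mean() - slope * x.mean()
        assert m.slope == pytest.approx(slope, rel=1e-9)
        assert m.intercept == pytest.approx(intercept, rel=1e-9)

    def test_too_few_shared_peptides(self):
        rt = pd.Series([10.0, 20, 30], index=list("abc"))
        with pytest.raises(ValueError, match="identity"):
            dia.fit_rt_map(rt, rt)


# ---------------------------------------------------------------------------
# cross-run extraction
# ---------------------------------------------------------------------------

class TestExtraction:
    def test_noiseless_roundtrip_and_truly_absent(self):
        """A peptide undetected in one run but with identical signal present
        extracts to the value it would have measured; a truly absent peptide
        extracts to zero."""
        from rttomics import simulate
        cfg = simulate.DiaSimConfig(
            n_proteins=10, peptides_per_protein=(3, 3), noise_cv=0.0,
            drift_scale=0.0, missing_rate=0.0, rt_shift_sd_minutes=0.0,
            rt_slope_sd=0.0, frac_changed=0.0, seed=2,
        )
        exp = simulate.simulate_dia_experiment(cfg)
        full = dia.quantify_runs(exp.traces, exp.detections)
        # hide one measured peptide from one run, then extract it back
        pep = full.peptides[0]
        run = full.runs[1]
        expected = full.values.loc[pep, run]
        detections = exp.detections.copy()
        detections.loc[pep, run] = False
        hidden = dia.quantify_runs(exp.traces, detections)
        assert hidden.status.loc[pep, run] == dia.ABSENT
        rt_maps = {r: dia.identity_rt_map() for r in hidden.runs}
        filled = dia.extract_missing_peptides(hidden, exp.traces, rt_maps)
        assert filled.status.loc[pep, run] == dia.EXTRACTED
        assert filled.values.loc[pep, run] == pytest.approx(expected, rel=1e-3)
        # measured cells untouched
        other = [r for r in filled.runs if r != run]
        assert (filled.values.loc[pep, other] ==
                hidden.values.loc[pep, other]).all()
        # truly absent signal: empty traces for that run -> 0
        gone = dia.extract_missing_peptides(
            hidden, exp.traces[exp.traces["run_id"] != run], rt_maps
        )
        assert gone.values.loc[pep, run] == 0.0
        assert gone.status.loc[pep, run] == dia.EXTRACTED

    def test_extracted_values_track_truth(self, tiny_experiment, tiny_quant):
        matrix, _ = tiny_quant
        exp = tiny_experiment
        mask = matrix.status == dia.EXTRACTED
        if mask.to_numpy().sum() < 3:
            pytest.skip("too few extracted cells in fixture")
        est, truth = [], []
        for pep in matrix.peptides:
            for run in matrix.runs:
                if mask.loc[pep, run] and matrix.values.loc[pep, run] > 0:
                    est.append(matrix.values.loc[pep, run])
                    truth.append(exp.ledger.true_abundance.loc[pep, run])
        rho = stats.spearmanr(est, truth).statistic
        assert rho > 0.8


# ---------------------------------------------------------------------------
# normalization / rescaling
# ---------------------------------------------------------------------------

class TestNormalization:
    def test_constant_run_scaling_removed_exactly(self, simple_matrix):
        """Scaling one run by a constant changes nothing after normalization
        and min-1 rescaling (the constant leaks only into a global factor)."""
        scaled = simple_matrix.copy()
        scaled.values["mut_1"] *= 2.0
        norm = dia.normalize_matrix(scaled, max_normalizers=3)
        base = dia.normalize_matrix(simple_matrix, max_normalizers=3)
        ratio = (norm.values / base.values).to_numpy()
        assert np.allclose(ratio, ratio.ravel()[0])  # one global constant
        pd.testing.assert_frame_equal(
            dia.rescale_relative(norm).values,
            dia.rescale_relative(base).values,
        )

    def test_two_identical_runs_scaled_by_two(self):
        runs = ["a", "b"]
        peps = [f"P{i}" for i in range(10)]
        vals = pd.DataFrame(
            {"a": np.linspace(10, 100, 10), "b": 2 * np.linspace(10, 100, 10)},
            index=peps,
        )
        status = pd.DataFrame(dia.MEASURED, index=peps, columns=runs)
        apex = pd.DataFrame(
            np.tile(np.linspace(10, 80, 10)[:, None], (1, 2)),
            index=peps, columns=runs,
        )
        m = dia.PeptideAbundanceMatrix(vals, status, apex)
        norm = dia.normalize_matrix(m)
        assert np.allclose(norm.values["a"], norm.values["b"])

    def test_error_when_no_candidates(self, simple_matrix):
        m = simple_matrix.copy()
        m.status.loc[:, "mut_2"] = dia.EXTRACTED
        with pytest.raises(ValueError, match="mut_2"):
            dia.normalize_matrix(m)

    def test_driftfree_simulation_close_to_identity(self):
        from rttomics import simulate
        cfg = simulate.DiaSimConfig(
            n_proteins=40, drift_scale=0.0, noise_cv=0.02, missing_rate=0.0,
            frac_changed=0.0, seed=4,
        )
        exp = simulate.simulate_dia_experiment(cfg)
        matrix = dia.quantify_runs(exp.traces, exp.detections)
        norm = dia.normalize_matrix(matrix)
        log_ratio = np.log(norm.values.to_numpy() / matrix.values.to_numpy())
        assert np.median(np.abs(log_ratio)) < 0.05


class TestRescale:
    def test_examples(self):
        vals = pd.DataFrame([[2.0, 4.0], [8.0, 16.0]],
                            index=["p", "q"], columns=["a", "b"])
        m = matrix_from_values(vals)
        out = dia.rescale_relative(m)
        assert out.values.to_numpy().tolist() == [[1.0, 2.0], [4.0, 8.0]]
        again = dia.rescale_relative(out)
        pd.testing.assert_frame_equal(again.values, out.values)

    def test_nonpositive_error(self):
        vals = pd.DataFrame([[0.0, 4.0]], index=["p"], columns=["a", "b"])
        m = matrix_from_values(vals)
        with pytest.raises(ValueError, match="non-positive"):
            dia.rescale_relative(m)

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(1e-3, 1e6), min_size=2, max_size=40))
    def test_min_one_and_ratios_preserved(self, flat):
        n = len(flat) // 2 * 2
        if n < 2:
            return
        vals = pd.DataFrame(np.array(flat[:n]).reshape(-1, 2),
                            columns=["a", "b"])
        m = matrix_from_values(vals)
        out = dia.rescale_relative(m)
        assert np.nanmin(out.values.to_numpy()) == 1.0
        r_in = vals.to_numpy().ravel() / vals.to_numpy().ravel()[0]
        r_out = out.values.to_numpy().ravel() / out.values.to_numpy().ravel()[0]
        assert np.allclose(r_in, r_out, rtol=1e-12)


# ---------------------------------------------------------------------------
# shared peptides, roll-up, significance
# ---------------------------------------------------------------------------

class TestSharedPeptides:
    def test_majority_vote(self):
        rows = [("pep1", f"r{i}", "P1") for i in range(4)] + \
               [("pep1", f"r{i}", "P2") for i in range(2)]
        df = pd.DataFrame(rows, columns=["peptide_id", "run_id", "protein_acc"])
        assert dia.resolve_shared_peptides(df)["pep1"] == "P1"

    def test_consistent_assignment_unchanged(self):
        df = pd.DataFrame([("pep1", "r1", "P9")],
                          columns=["peptide_id", "run_id", "protein_acc"])
        assert dia.resolve_shared_peptides(df)["pep1"] == "P9"

    def test_tie_breaks_lexicographically(self):
        rows = [("pep1", f"r{i}", "P2") for i in range(3)] + \
               [("pep1", f"r{i + 3}", "P1") for i in range(3)]
        df = pd.DataFrame(rows, columns=["peptide_id", "run_id", "protein_acc"])
        assert dia.resolve_shared_peptides(df)["pep1"] == "P1"


def matrix_from_values(values, status=None):
    if status is None:
        status = pd.DataFrame(dia.MEASURED, index=values.index,
                              columns=values.columns)
    apex = pd.DataFrame(30.0, index=values.index, columns=values.columns)
    return dia.PeptideAbundanceMatrix(values, status, apex)


class TestRollup:
    groups = {"c1": "control", "c2": "control", "m1": "mutant", "m2": "mutant"}

    def test_median_of_peptide_ratios(self):
        # ratios 2, 2, 4 -> median 2 -> signed FC +2
        vals = pd.DataFrame(
            {"c1": [10.0, 20.0, 5.0], "c2": [10.0, 20.0, 5.0],
             "m1": [20.0, 40.0, 20.0], "m2": [20.0, 40.0, 20.0]},
            index=["p1", "p2", "p3"],
        )
        pmap = pd.DataFrame({
            "peptide_id": ["p1", "p2", "p3"],
            "protein_acc": "PROT", "modification": "none",
        })
        out = dia.rollup_protein(matrix_from_values(vals), pmap, self.groups)
        assert len(out) == 1
        assert out.loc[0, "fold_change"] == pytest.approx(2.0)
        assert out.loc[0, "n_peptides"] == 3
        assert out.loc[0, "mode"] == dia.COMPLETE_PEPTIDES

    def test_sign_convention_for_decrease(self):
        vals = pd.DataFrame(
            {"c1": [10.0], "c2": [10.0], "m1": [5.0], "m2": [5.0]},
            index=["p1"],
        )
        pmap = pd.DataFrame({"peptide_id": ["p1"], "protein_acc": "PROT",
                             "modification": "none"})
        out = dia.rollup_protein(matrix_from_values(vals), pmap, self.groups)
        assert out.loc[0, "fold_change"] == pytest.approx(-2.0)

    def test_pooled_pvalue_matches_textbook_ttest(self):
        rng = np.random.default_rng(5)
        a = rng.lognormal(3, 0.2, 4)
        b = rng.lognormal(3.4, 0.2, 4)
        vals = pd.DataFrame([np.concatenate([a, b])], index=["p1"],
                            columns=["c1", "c2", "c3", "c4",
                                     "m1", "m2", "m3", "m4"])
        groups = {c: ("control" if c.startswith("c") else "mutant")
                  for c in vals.columns}
        pmap = pd.DataFrame({"peptide_id": ["p1"], "protein_acc": "PROT",
                             "modification": "none"})
        out = dia.rollup_protein(matrix_from_values(vals), pmap, groups,
                                 ttest_method="pooled")
        # hand-computed classical pooled-variance two-sample t on log2 values
        la, lb = np.log2(a), np.log2(b)
        sp2 = (la.var(ddof=1) * 3 + lb.var(ddof=1) * 3) / 6
        t = (lb.mean() - la.mean()) / np.sqrt(sp2 * (1 / 4 + 1 / 4))
        p = 2 * stats.t.sf(abs(t), 6)
        assert out.loc[0, "p_value"] == pytest.approx(p, rel=1e-9)

    def test_ratio_pvalue_matches_one_sample_oracle(self):
        rng = np.random.default_rng(6)
        vals = pd.DataFrame(
            rng.lognormal(5, 0.1, size=(4, 8)),
            index=[f"p{i}" for i in range(4)],
            columns=["c1", "c2", "c3", "c4", "m1", "m2", "m3", "m4"],
        )
        groups = {c: ("control" if c.startswith("c") else "mutant")
                  for c in vals.columns}
        pmap = pd.DataFrame({"peptide_id": vals.index, "protein_acc": "PROT",
                             "modification": "none"})
        out = dia.rollup_protein(matrix_from_values(vals), pmap, groups,
                                 ttest_method="ratio")
        logs = np.log2(vals)
        ratios = logs.iloc[:, 4:].mean(axis=1) - logs.iloc[:, :4].mean(axis=1)
        p = stats.ttest_1samp(ratios, 0.0).pvalue
        assert out.loc[0, "p_value"] == pytest.approx(p, rel=1e-9)

    def test_ptm_forms_quantified_separately(self):
        vals = pd.DataFrame(
            {"c1": [10.0, 8.0], "c2": [10.0, 8.0],
             "m1": [20.0, 4.0], "m2": [20.0, 4.0]},
            index=["p1", "p2"],
        )
        pmap = pd.DataFrame({
            "peptide_id": ["p1", "p2"],
            "protein_acc": ["PROT", "PROT"],
            "modification": ["none", "acetyl"],
        })
        out = dia.rollup_protein(matrix_from_values(vals), pmap, self.groups)
        assert len(out) == 2
        by_form = out.set_index("form")["fold_change"]
        assert by_form["none"] == pytest.approx(2.0)
        assert by_form["acetyl"] == pytest.approx(-2.0)

    def test_incomplete_proteins_use_all_peptides(self):
        vals = pd.DataFrame(
            {"c1": [10.0], "c2": [np.nan], "m1": [20.0], "m2": [20.0]},
            index=["p1"],
        )
        status = pd.DataFrame(
            [[dia.MEASURED, dia.ABSENT, dia.MEASURED, dia.MEASURED]],
            index=["p1"], columns=vals.columns,
        )
        pmap = pd.DataFrame({"peptide_id": ["p1"], "protein_acc": "PROT",
                             "modification": "none"})
        out = dia.rollup_protein(matrix_from_values(vals, status), pmap,
                                 self.groups)
        assert out.loc[0, "mode"] == dia.ALL_PEPTIDES
        assert out.loc[0, "fold_change"] == pytest.approx(2.0)


class TestSignificantProteins:
    def test_strict_threshold(self):
        q = pd.DataFrame({"accession": ["A", "B"], "form": "none",
                          "n_peptides": 2, "mode": dia.COMPLETE_PEPTIDES,
                          "fold_change": [2.0, 2.0],
                          "p_value": [0.099, 0.1]})
        out = dia.significant_proteins(q, alpha=0.1)
        assert list(out["accession"]) == ["A"]


class TestSignedFold:
    def test_direction_agreement_and_magnitude(self, tiny_quant):
        _, quants = tiny_quant
        assert (quants["fold_change"].abs() >= 1).all()
        assert quants["p_value"].between(0, 1).all()
        assert (quants["n_peptides"] >= 1).all()
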