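"""Classification band, voting, screening metrics and the threshold sweep."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osteotap import decision as dc


class TestClassifyOutput:
    @pytest.mark.parametrize("o,tau,expected", [
        (0.3, 0.4, dc.OP),
        (0.5, 0.4, dc.AMBIGUOUS),
        (0.5, 0.5, dc.AMBIGUOUS),  # the exact midpoint is always ambiguous
        (0.0, 0.4, dc.OP),
        (1.0, 0.4, dc.OK),
        (0.4, 0.4, dc.OP),   # boundary inclusive
        (0.6, 0.4, dc.OK),   # boundary inclusive
        (0.45, 0.4, dc.AMBIGUOUS),
        (0.1, 0.2, dc.OP),
        (0.25, 0.2, dc.AMBIGUOUS),
    ])
    def test_symmetric_band_rule(self, o, tau, expected):
        assert dc.classify_output(o, tau) == expected

    @pytest.mark.parametrize("o,tau", [(-0.1, 0.4), (1.1, 0.4), (0.5, 0.0),
                                       (0.5, 0.6), (0.5, -0.2)])
    def test_out_of_range_rejected(self, o, tau):
        with pytest.raises(ValueError):
            dc.classify_output(o, tau)

    @settings(deadline=None, max_examples=200)
    @given(o=st.floats(0.0, 1.0), tau1=st.floats(0.01, 0.5),
           tau2=st.floats(0.01, 0.5))
    def test_enlarging_tau_never_undecides(self, o, tau1, tau2):
        lo, hi = sorted((tau1, tau2))
        if dc.classify_output(o, lo) != dc.AMBIGUOUS:
            assert dc.classify_output(o, hi) == dc.classify_output(o, lo)


def brute_force_vote(classes):
    """Independent majority oracle by explicit counting."""
    op = sum(1 for c in classes if c == dc.OP)
    ok = sum(1 for c in classes if c == dc.OK)
    if op == 0 and ok == 0:
        return dc.UNDETERMINED
    if op > ok:
        return dc.OP
    if ok > op:
        return dc.OK
    return dc.OP  # tie goes to the screening-positive class


class TestVoting:
    @pytest.mark.parametrize("classes,expected", [
        ([dc.OP, dc.OP, dc.OK], dc.OP),
        ([dc.AMBIGUOUS] * 4, dc.UNDETERMINED),
        ([dc.OP, dc.OK], dc.OP),  # tie rule
        ([dc.OK, dc.OK, dc.OP, dc.AMBIGUOUS], dc.OK),
    ])
    def test_documented_examples(self, classes, expected):
        assert dc.vote_patient(classes).final == expected

    def test_empty_decision_list_rejected(self):
        with pytest.raises(ValueError):
            dc.vote_patient([])

    def test_counts_sum_to_ir_count(self):
        diag = dc.vote_patient([dc.OP, dc.AMBIGUOUS, dc.OK, dc.OK])
        assert diag.n_op + diag.n_ok + diag.n_ambiguous == 4

    @pytest.mark.parametrize("n", [1, 2, 3, 4, 5])
    def test_agrees_with_enumeration_oracle(self, n):
        """Exhaustive agreement over every assignment of up to five IRs."""
        for classes in itertools.product([dc.OP, dc.OK, dc.AMBIGUOUS], repeat=n):
            assert dc.vote_patient(list(classes)).final == brute_force_vote(classes)


class TestMetrics:
    def test_validation_sensitivity_cell(self):
        """8 of 11 positive IRs hit -> TPR 0.7273."""
        m = dc.ConfusionMetrics.from_counts(tp=8, fp=4, tn=31, fn=3)
        assert round(m.tpr, 4) == 0.7273
        assert round(m.fpr, 4) == 0.1143

    def test_patient_fpr_cell(self):
        """1 false positive among 9 healthy patients -> FPR 0.1111."""
        m = dc.ConfusionMetrics.from_counts(tp=3, fp=1, tn=8, fn=0)
        assert round(m.fpr, 4) == 0.1111
        assert m.tpr == 1.0

    def test_perfect_classifier(self):
        m = dc.ConfusionMetrics.from_counts(tp=5, fp=0, tn=7, fn=0)
        assert (m.tpr, m.fpr, m.spc, m.acc) == (1.0, 0.0, 1.0, 1.0)
        assert m.r == 0.0

    def test_ratio_undefined_without_true_positives(self):
        m = dc.ConfusionMetrics.from_counts(tp=0, fp=2, tn=5, fn=3)
        assert math.isnan(m.r)

    @settings(deadline=None, max_examples=100)
    @given(tp=st.integers(0, 50), fp=st.integers(0, 50),
           tn=st.integers(0, 50), fn=st.integers(0, 50))
    def test_identities_hold_for_any_counts(self, tp, fp, tn, fn):
        m = dc.ConfusionMetrics.from_counts(tp, fp, tn, fn)
        assert m.p == tp + fn and m.n == tn + fp
        if m.n:
            assert m.spc == pytest.approx(1.0 - m.fpr, abs=1e-15)
        if m.p and m.n:
            weighted = (m.tpr * m.p + m.spc * m.n) / (m.p + m.n)
            assert m.acc == pytest.approx(weighted, abs=1e-12)

    def test_undetermined_entries_excluded_and_counted(self):
        pred = [dc.OP, dc.UNDETERMINED, dc.OK, dc.AMBIGUOUS]
        truth = [dc.OP, dc.OP, dc.OK, dc.OK]
        m, excluded = dc.compute_metrics(pred, truth)
        assert excluded == 2
        assert (m.tp, m.tn) == (1, 1)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dc.compute_metrics([dc.OP], [dc.OP, dc.OK])


class TestErrorBound:
    def test_half_energy_50_over_330_bounds_30_percent(self):
        rate = dc.max_misclassification_rate(50.0, 330)
        assert rate == pytest.approx(100 / 330, rel=1e-12)
        assert round(rate * 100) == 30

    def test_bound_saturates_at_one(self):
        assert dc.max_misclassification_rate(1000.0, 10) == 1.0

    @pytest.mark.parametrize("e,m", [(-1.0, 10), (5.0, 0)])
    def test_invalid_inputs_rejected(self, e, m):
        with pytest.raises(ValueError):
            dc.max_misclassification_rate(e, m)


def _toy_dataset():
    """Six patients x four IRs with outputs spread across the unit interval."""
    rng = np.random.default_rng(0)
    pids, teachers, outputs = [], [], []
    for i in range(6):
        op = i < 2
        for _ in range(4):
            pids.append(f"P{i}")
            teachers.append(0.0 if op else 1.0)
            centre = 0.15 if op else 0.85
            outputs.append(float(np.clip(centre + 0.2 * rng.normal(), 0.001, 0.999)))
    return np.array(outputs), np.array(teachers), pids


class TestSweep:
    def test_default_range_has_61_rows(self):
        out, t, pids = _toy_dataset()
        sweep = dc.threshold_sweep(None, (None, t, pids), outputs=out)
        assert len(sweep) == 61
        assert sweep["threshold"].iloc[0] == 0.2
        assert sweep["threshold"].iloc[-1] == 0.5
        assert sweep["threshold"].is_monotonic_increasing

    def test_single_threshold_range(self):
        out, t, pids = _toy_dataset()
        sweep = dc.threshold_sweep(None, (None, t, pids), tau_start=0.4,
                                   tau_end=0.4, outputs=out)
        assert len(sweep) == 1

    def test_invalid_range_rejected(self):
        out, t, pids = _toy_dataset()
        with pytest.raises(ValueError):
            dc.threshold_sweep(None, (None, t, pids), tau_start=0.5,
                               tau_end=0.2, outputs=out)

    def test_ambiguous_count_shrinks_as_tau_grows(self):
        out, t, pids = _toy_dataset()
        sweep = dc.threshold_sweep(None, (None, t, pids), outputs=out)
        assert np.all(np.diff(sweep["ir_ambiguous"]) <= 0)

    def test_class_counts_conserved_at_every_threshold(self):
        out, t, pids = _toy_dataset()
        for tau in (0.2, 0.35, 0.5):
            classes = dc.classify_outputs(out, tau)
            assert (classes.count(dc.OP) + classes.count(dc.OK)
                    + classes.count(dc.AMBIGUOUS)) == len(out)

    def test_table_columns_cover_both_levels(self):
        out, t, pids = _toy_dataset()
        table = dc.sweep_table(dc.threshold_sweep(None, (None, t, pids), outputs=out))
        assert list(table.columns) == ["threshold", "ir_tpr", "ir_fpr",
                                       "pat_tpr", "pat_fpr"]

    def test_best_row_prefers_sensitivity_among_equal_ratios(self):
        sweep = pd.DataFrame({
            "threshold": [0.2, 0.3, 0.4],
            "pat_tpr": [0.5, 1.0, 0.8],
            "pat_fpr": [0.0, 0.0, 0.1],
            "pat_r": [0.0, 0.0, 0.125],
        })
        best = dc.best_sweep_row(sweep)
        assert best["threshold"] == 0.3
        assert best["pat_tpr"] == 1.0


class TestRocExport:
    def test_row_count_preserved(self, tmp_path):
        out, t, pids = _toy_dataset()
        sweep = dc.threshold_sweep(None, (None, t, pids), outputs=out)
        roc = dc.export_roc(sweep, tmp_path / "roc.csv")
        assert len(roc) == 61
        assert (tmp_path / "roc.csv").exists()

    def test_separable_cohort_reaches_ideal_corner(self, tmp_path):
        outputs = np.array([0.05] * 4 + [0.95] * 8)
        teachers = np.array([0.0] * 4 + [1.0] * 8)
        pids = ["A", "A", "B", "B", "C", "C", "D", "D", "E", "E", "F", "F"]
        sweep = dc.threshold_sweep(None, (None, teachers, pids), outputs=outputs)
        roc = dc.export_roc(sweep, tmp_path / "roc.csv")
        corner = roc[(roc["pat_sen"] == 1.0) & (roc["pat_one_minus_spc"] == 0.0)]
        assert len(corner) > 0

    def test_all_ambiguous_rows_flagged_not_dropped(self, tmp_path):
        outputs = np.full(8, 0.5)
        teachers = np.array([0.0] * 4 + [1.0] * 4)
        pids = ["A", "A", "B", "B", "C", "C", "D", "D"]
        sweep = dc.threshold_sweep(None, (None, teachers, pids), outputs=outputs)
        roc = dc.export_roc(sweep, tmp_path / "roc.csv")
        assert len(roc) == len(sweep)
        assert not roc["defined"].any()

    def test_empty_sweep_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            dc.export_roc(pd.DataFrame(), tmp_path / "roc.csv")
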