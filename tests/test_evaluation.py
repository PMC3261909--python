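import datetime
import math

import pytest

from textscm.corpus_io import TrainingPartition
from textscm.errors import EvaluationError
from textscm.evaluation import (confusion, evaluate_labels, loo_cv, metrics,
                                patient_level, proportion_ci)
from textscm.experiments import separable_loocv_partition
from textscm.scm_core import ScoreParams

from conftest import rec


def wilson_reference(k, n, z=1.959963984540054):
    """Closed-form Wilson score interval (oracle for proportion_ci)."""
    phat = k / n
    denom = 1 + z * z / n
    centre = (phat + z * z / (2 * n)) / denom
    half = z * math.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n)) / denom
    return 100 * (centre - half), 100 * (centre + half)


class TestConfusion:
    def test_all_positive_agreement(self):
        pred = {f"r{i}": True for i in range(5)}
        assert confusion(pred, dict(pred)) == (5, 0, 0, 0)

    def test_total_disagreement(self):
        pred = {"a": True, "b": True, "c": False, "d": False}
        gold = {"a": False, "b": False, "c": True, "d": True}
        assert confusion(pred, gold) == (0, 2, 2, 0)

    def test_empty_input(self):
        assert confusion({}, {}) == (0, 0, 0, 0)

    def test_key_mismatch_lists_difference(self):
        with pytest.raises(EvaluationError, match="r2"):
            confusion({"r1": True}, {"r1": True, "r2": False})


class TestMetrics:
    def test_angiogram_worked_example(self):
        rep = metrics(96, 55, 15)
        assert (rep.precision, rep.recall, rep.f_score) == (63.6, 86.5, 73.3)

    def test_ovarian_worked_example(self):
        rep = metrics(303, 106, 50)
        assert (rep.precision, rep.recall, rep.f_score) == (74.1, 85.8, 79.5)

    def test_undefined_precision_is_none_not_zero(self):
        with pytest.warns(UserWarning, match="precision undefined"):
            rep = metrics(0, 0, 7)
        assert rep.precision is None
        assert rep.recall == 0.0

    def test_f_between_min_and_max_of_p_and_r(self):
        for tp, fp, fn in [(96, 55, 15), (67, 19, 44), (2, 64, 109),
                           (218, 38, 134)]:
            rep = metrics(tp, fp, fn)
            assert min(rep.precision, rep.recall) <= rep.f_score
            assert rep.f_score <= max(rep.precision, rep.recall)

    def test_rounding_half_away_from_zero(self):
        # 11/16 = 68.75 -> 68.8 under half-away-from-zero
        assert metrics(11, 5, 0).precision == 68.8

    def test_negative_counts_rejected(self):
        with pytest.raises(EvaluationError):
            metrics(-1, 0, 0)


class TestProportionCi:
    def test_boundaries(self):
        lo, _ = proportion_ci(0, 10)
        _, hi = proportion_ci(10, 10)
        assert lo == 0.0
        assert hi == 100.0

    @pytest.mark.parametrize("k,n", [(96, 151), (67, 86), (96, 111),
                                     (1, 30), (29, 30)])
    def test_matches_closed_form_wilson(self, k, n):
        got = proportion_ci(k, n)
        want = wilson_reference(k, n)
        assert got == pytest.approx(want, abs=1e-9)

    def test_zero_trials_rejected(self):
        with pytest.raises(EvaluationError):
            proportion_ci(0, 0)


class TestLooCv:
    def test_separable_fixture_perfect(self):
        """Every held-out positive shares its planted combination with two
        other positives, so it is always recovered."""
        part = separable_loocv_partition()
        assert loo_cv(part, ScoreParams(q0=0.2, T=2)) == 0.0

    def test_two_disjoint_positives_always_fail(self):
        P = (rec("p0", "aa bb", "positive"), rec("p1", "cc dd", "positive"))
        part = TrainingPartition(P=P, U=(), N=(rec("n0", "x", "negative"),))
        with pytest.warns(UserWarning, match="no candidate"):
            assert loo_cv(part, ScoreParams(T=1)) == 1.0

    def test_invariant_to_fold_order(self):
        part = separable_loocv_partition()
        shuffled = TrainingPartition(P=part.P[::-1], U=part.U, N=part.N)
        params = ScoreParams(q0=0.2, T=1)
        assert loo_cv(part, params) == loo_cv(shuffled, params)

    def test_needs_two_positives(self):
        part = TrainingPartition(P=(rec("p0", "a", "positive"),), U=(), N=())
        with pytest.raises(EvaluationError):
            loo_cv(part, ScoreParams())


def d(day):
    return datetime.date(2004, 1, day)


class TestPatientLevel:
    def test_min_date_logic(self):
        records = [
            rec("r1", "a", patient_id="pt1", event_date=d(3), gold=True),
            rec("r2", "b", patient_id="pt1", event_date=d(1), gold=True),
        ]
        report = patient_level(records, {"r1": False, "r2": True},
                               {"r1": True, "r2": False})
        row = report.table.iloc[0]
        assert row["algorithm_date"] == d(1)
        assert row["code_date"] == d(3)
        assert report.n_algorithm_earlier == 1

    def test_undetected_patient(self):
        records = [rec("r1", "a", patient_id="pt1", event_date=d(1),
                       gold=False)]
        report = patient_level(records, {"r1": False}, {"r1": False})
        row = report.table.iloc[0]
        assert not row["algorithm"] and not row["codes"]

    def test_missing_dates_counted_but_not_timed(self):
        records = [rec("r1", "a", patient_id="pt1", gold=True)]
        with pytest.warns(UserWarning, match="undated"):
            report = patient_level(records, {"r1": True}, {"r1": True})
        row = report.table.iloc[0]
        assert row["algorithm"] and row["algorithm_date"] is None
        assert report.n_patients_without_dates == 1

    def test_missing_patient_id_rejected(self):
        with pytest.raises(EvaluationError):
            patient_level([rec("r1", "a")], {"r1": True}, {"r1": False})

    def test_code_recall_gap_cohort(self, rng):
        """Cohort where ~80% of case patients carry a code but all carry
        textual evidence: code recall ~80%, algorithm recall higher."""
        records, pred, flags = [], {}, {}
        for i in range(50):
            has_code = i < 40
            records.append(rec(f"r{i}", "evid", patient_id=f"pt{i}",
                               event_date=d(2), gold=True))
            pred[f"r{i}"] = True
            flags[f"r{i}"] = has_code
        report = patient_level(records, pred, flags)
        assert report.codes.recall == 80.0
        assert report.algorithm.recall == 100.0
        assert report.algorithm.recall > report.codes.recall


def test_evaluate_labels_end_to_end():
    pred = {"a": True, "b": True, "c": False}
    gold = {"a": True, "b": False, "c": True}
    rep = evaluate_labels(pred, gold)
    assert (rep.tp, rep.fp, rep.fn, rep.tn) == (1, 1, 1, 0)
    assert rep.precision == 50.0 and rep.recall == 50.0
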