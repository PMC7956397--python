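"""Reference windowization, confusion matrices, error metrics, aggregation."""

import math

import numpy as np
import pytest

from hfital import (
    ActivityLabel,
    LabelSeries,
    ReferenceEvents,
    cohort_summary,
    confusion,
    percentage_error,
    sens_spec_acc,
    subject_report,
    total_error,
    windowize_reference,
)
from hfital.metrics import ConfusionCounts, is_acceptable

from oracles import confusion_loop, net_relabel_count, quartiles_sorted, total_errors_loop, windowize_loop

SED, STAND, DYN = ActivityLabel.SEDENTARY, ActivityLabel.STANDING, ActivityLabel.DYNAMIC


def series(labels, ws=4.0, subject_id="s"):
    return LabelSeries(np.array([int(v) for v in labels]), ws_seconds=ws, subject_id=subject_id)


def random_events(rng, total_s, ws):
    """Random contiguous event table covering [0, total_s]."""
    labels, durs = [], []
    t = 0.0
    while t < total_s:
        labels.append(int(rng.integers(0, 3)))
        d = float(rng.uniform(0.5, 3.5) * ws)
        durs.append(min(d, total_s - t))
        t += durs[-1]
    return ReferenceEvents.from_segments(zip([ActivityLabel(v) for v in labels], durs))


class TestReferenceEvents:
    def test_gap_rejected(self):
        with pytest.raises(ValueError, match="not contiguous"):
            ReferenceEvents(labels=[SED, DYN], onsets=[0.0, 5.0], offsets=[4.0, 9.0])

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="not contiguous"):
            ReferenceEvents(labels=[SED, DYN], onsets=[0.0, 3.0], offsets=[4.0, 9.0])

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            ReferenceEvents(labels=[SED], onsets=[2.0], offsets=[2.0])


class TestWindowizeReference:
    def test_window_inside_single_event(self):
        events = ReferenceEvents.from_segments([(STAND, 40.0)])
        out = windowize_reference(events, 4.0, 10)
        assert set(out) == {STAND}

    def test_majority_duration_wins(self):
        # 2.5 s standing then 1.5 s dynamic inside one 4 s window
        events = ReferenceEvents.from_segments([(STAND, 2.5), (DYN, 1.5)])
        assert windowize_reference(events, 4.0, 1)[0] is STAND

    def test_exact_tie_breaks_to_later_event(self):
        events = ReferenceEvents.from_segments([(SED, 2.0), (DYN, 2.0)])
        assert windowize_reference(events, 4.0, 1)[0] is DYN

    def test_insufficient_coverage_rejected(self):
        events = ReferenceEvents.from_segments([(SED, 30.0)])
        with pytest.raises(ValueError, match="cover"):
            windowize_reference(events, 4.0, 10)

    @pytest.mark.parametrize("ws", [0.4, 2.0, 4.0])
    def test_matches_duration_accumulation_oracle(self, rng, ws):
        for _ in range(20):
            n_windows = int(rng.integers(5, 40))
            events = random_events(rng, n_windows * ws + ws, ws)
            got = windowize_reference(events, ws, n_windows)
            expected = windowize_loop(events.labels, events.onsets, events.offsets, ws, n_windows)
            assert got.labels.tolist() == expected


class TestConfusion:
    def test_perfect_agreement_has_no_errors(self, rng):
        labels = series(rng.integers(0, 3, 50))
        for target in ActivityLabel:
            c = confusion(labels, labels, target)
            assert c.fp == 0 and c.fn == 0
            assert c.total == 50

    def test_dynamic_example(self):
        algo = series([DYN, DYN, STAND, SED])
        ref = series([DYN, STAND, STAND, SED])
        c = confusion(algo, ref, DYN)
        assert (c.tp, c.fp, c.tn, c.fn) == (1, 1, 2, 0)

    def test_transition_false_positive(self):
        c = confusion(series([SED, STAND]), series([SED, SED]), "transitions")
        assert (c.tp, c.fp, c.tn, c.fn) == (0, 1, 0, 0)
        assert c.total == 1  # one boundary between two windows

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="lengths differ"):
            confusion(series([SED]), series([SED, SED]), SED)

    def test_random_pairs_match_counting_loop(self, rng):
        for _ in range(30):
            n = int(rng.integers(10, 200))
            a, r = rng.integers(0, 3, n), rng.integers(0, 3, n)
            for target in (0, 1, 2):
                c = confusion(series(a), series(r), ActivityLabel(target))
                assert (c.tp, c.fp, c.tn, c.fn) == confusion_loop(a.tolist(), r.tolist(), target)

    def test_one_vs_rest_matrices_pool_to_micro_average(self, rng):
        n = 200
        a, r = rng.integers(0, 3, n), rng.integers(0, 3, n)
        cs = [confusion(series(a), series(r), ActivityLabel(t)) for t in range(3)]
        total = cs[0] + cs[1] + cs[2]
        assert total.tp + total.fn == n  # every window is positive for exactly one class
        _, _, acc = sens_spec_acc(total)
        # micro-average over the three one-vs-rest binarizations
        direct = 100.0 * np.mean([np.mean((a == t) == (r == t)) for t in range(3)])
        assert acc == pytest.approx(direct)


class TestSensSpecAcc:
    def test_arithmetic_example(self):
        sens, spec, acc = sens_spec_acc(ConfusionCounts(tp=9, fn=1, tn=5, fp=5))
        assert (sens, spec, acc) == (90.0, 50.0, 70.0)

    def test_perfect(self):
        assert sens_spec_acc(ConfusionCounts(tp=10, fn=0, tn=10, fp=0)) == (100.0, 100.0, 100.0)

    def test_zero_denominator_is_not_available(self):
        sens, spec, acc = sens_spec_acc(ConfusionCounts(tp=0, fn=0, tn=5, fp=5))
        assert math.isnan(sens) and spec == 50.0 and acc == 50.0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sens_spec_acc(ConfusionCounts(tp=0, fn=0, tn=0, fp=0))


class TestPercentageError:
    def test_overestimation_is_negative(self):
        pe, ape = percentage_error(100.0, 120.0)
        assert pe == -20.0 and ape == 20.0

    def test_equal_quantities(self):
        assert percentage_error(50.0, 50.0) == (0.0, 0.0)

    def test_transition_count_example(self):
        pe, ape = percentage_error(1, 3)
        assert pe == -200.0 and ape == 200.0

    def test_zero_reference_is_not_available(self):
        pe, ape = percentage_error(0.0, 10.0)
        assert math.isnan(pe) and math.isnan(ape)


class TestTotalError:
    def test_telescoping_on_shared_grid(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 100))
            a, r = series(rng.integers(0, 3, n)), series(rng.integers(0, 3, n))
            ref_t = [r.time_s(ActivityLabel(k)) for k in range(3)]
            algo_t = [a.time_s(ActivityLabel(k)) for k in range(3)]
            pe, _ = total_error(ref_t, algo_t)
            assert pe == 0.0

    def test_arithmetic_example(self):
        pe, ape = total_error([100.0, 50.0, 50.0], [110.0, 50.0, 40.0])
        assert pe == 0.0 and ape == 10.0

    def test_matches_disagreement_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 100))
            a, r = rng.integers(0, 3, n), rng.integers(0, 3, n)
            sa, sr = series(a), series(r)
            ref_t = [sr.time_s(ActivityLabel(k)) for k in range(3)]
            algo_t = [sa.time_s(ActivityLabel(k)) for k in range(3)]
            got = total_error(ref_t, algo_t)
            assert got == pytest.approx(total_errors_loop(a.tolist(), r.tolist(), 4.0))

    def test_net_relabel_identity_and_gross_bound(self, rng):
        ws = 4.0
        for _ in range(20):
            n = int(rng.integers(5, 100))
            a, r = rng.integers(0, 3, n), rng.integers(0, 3, n)
            sa, sr = series(a), series(r)
            _, ape = total_error(
                [sr.time_s(ActivityLabel(k)) for k in range(3)],
                [sa.time_s(ActivityLabel(k)) for k in range(3)],
            )
            net = net_relabel_count(a.tolist(), r.tolist())
            assert ape == pytest.approx(2.0 * net * ws / (n * ws) * 100.0)
            gross = int(np.sum(a != r))
            assert ape <= 2.0 * gross * ws / (n * ws) * 100.0 + 1e-9


class TestSubjectReport:
    def test_perfect_subject(self):
        ref = ReferenceEvents.from_segments([(SED, 20.0), (DYN, 20.0), (STAND, 20.0)])
        algo = series([SED] * 5 + [DYN] * 5 + [STAND] * 5)
        report = subject_report(algo, ref)
        for cat in ("sedentary", "standing", "dynamic", "total", "transitions"):
            row = report.rows[cat]
            for metric in ("sensitivity_pct", "specificity_pct", "accuracy_pct"):
                value = row.get(metric)
                assert math.isnan(value) or value == 100.0
            assert row.pe_pct == 0.0 and row.ape_pct == 0.0

    def test_single_flip_creates_transition_false_positive(self):
        ref = ReferenceEvents.from_segments([(SED, 20.0), (STAND, 20.0)])
        # one mid-bout sedentary window flipped to standing
        algo = series([SED, SED, STAND, SED, SED] + [STAND] * 5)
        report = subject_report(algo, ref)
        assert report.confusions["transitions"].fp == 1
        assert report.confusions["transitions"].tp == 1
        assert report.rows["transitions"].pe_pct < 0  # extra transition = overestimation

    def test_ape_is_absolute_pe(self, rng):
        ref = random_events(rng, 124.0, 4.0)
        algo = series(rng.integers(0, 3, 30))
        report = subject_report(algo, ref)
        for cat in ("sedentary", "standing", "dynamic", "transitions"):
            row = report.rows[cat]
            if not math.isnan(row.pe_pct):
                assert row.ape_pct == abs(row.pe_pct)
        assert report.rows["total"].ape_pct >= abs(report.rows["total"].pe_pct)

    def test_permutation_equivariance(self, rng):
        """Identically reordering windows in both series changes nothing."""
        n = 60
        a, r = rng.integers(0, 3, n), rng.integers(0, 3, n)
        perm = rng.permutation(n)
        for target in ActivityLabel:
            c1 = confusion(series(a), series(r), target)
            c2 = confusion(series(a[perm]), series(r[perm]), target)
            assert (c1.tp, c1.fp, c1.tn, c1.fn) == (c2.tp, c2.fp, c2.tn, c2.fn)


class TestCohortSummary:
    def _report(self, rng, n=30):
        ref = random_events(rng, n * 4.0 + 4.0, 4.0)
        return subject_report(series(rng.integers(0, 3, n)), ref)

    def test_single_report_collapses_quartiles(self, rng):
        summary = cohort_summary([self._report(rng)])
        q = summary.get("total", "accuracy_pct")
        assert q.median == q.q1 == q.q3

    def test_median_of_three(self):
        ref = ReferenceEvents.from_segments([(SED, 20.0), (DYN, 20.0)])
        reports = []
        for flips in (0, 1, 2):
            labels = [SED] * 5 + [DYN] * 5
            for i in range(flips):
                labels[i] = STAND
            reports.append(subject_report(series(labels), ref))
        summary = cohort_summary(reports)
        # median of three distinct per-subject accuracies is the middle one
        middle = reports[1].rows["total"].accuracy_pct
        assert sorted(r.rows["total"].accuracy_pct for r in reports)[1] == middle
        assert summary.get("total", "accuracy_pct").median == pytest.approx(middle)

    def test_quartiles_match_sort_oracle(self, rng):
        reports = [self._report(rng) for _ in range(9)]
        summary = cohort_summary(reports)
        values = [r.rows["total"].ape_pct for r in reports]
        q1, med, q3 = quartiles_sorted(values)
        got = summary.get("total", "ape_pct")
        assert (got.q1, got.median, got.q3) == pytest.approx((q1, med, q3))
        assert got.q1 <= got.median <= got.q3

    def test_not_available_values_are_excluded(self):
        # no reference standing time -> standing PE undefined for that subject
        ref_no_stand = ReferenceEvents.from_segments([(SED, 20.0), (DYN, 20.0)])
        ref_with_stand = ReferenceEvents.from_segments([(SED, 20.0), (STAND, 20.0)])
        r1 = subject_report(series([SED] * 5 + [DYN] * 5), ref_no_stand)
        r2 = subject_report(series([SED] * 5 + [STAND] * 5), ref_with_stand)
        assert math.isnan(r1.rows["standing"].pe_pct)
        summary = cohort_summary([r1, r2])
        assert summary.get("standing", "pe_pct").n_defined == 1
        assert summary.get("standing", "pe_pct").median == 0.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            cohort_summary([])


class TestAcceptability:
    @pytest.mark.parametrize(
        "metric, value, expected",
        [
            ("sensitivity_pct", 80.0, True),
            ("accuracy_pct", 79.9, False),
            ("pe_pct", -10.0, True),
            ("pe_pct", 10.1, False),
            ("ape_pct", 9.9, True),
            ("ape_pct", 10.0, False),
        ],
    )
    def test_limits(self, metric, value, expected):
        assert is_acceptable(metric, value) is expected

    def test_not_available_is_none(self):
        assert is_acceptable("pe_pct", math.nan) is None
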