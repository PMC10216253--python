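"""Session-log parsing, FR/timeout semantics and acquisition classifiers."""

import io
import math

import numpy as np
import pytest

from conftest import make_history
from nicodose.sessions import (
    AcquisitionCriteria,
    AcquisitionOutcome,
    CoverageError,
    DegenerateSDError,
    SessionLog,
    SessionParseError,
    SubjectHistory,
    classify_control_referenced,
    classify_low_dose,
    classify_standard_dose,
    control_referenced_cutoff,
    infusion_times,
    parse_session_log,
    phase_mean_infusions,
    session_summary,
    substitution_effect,
    validate_schedule_semantics,
    write_session_log,
)

LOG_TEXT = """\
# subject=S1
# group=g
# day=1
# dose_ug_per_kg=30
# fr=3
# timeout_s=20
# session_min=120
t_sec,kind
10,active
11,active
12,active
12,infusion
"""


class TestParsing:
    def test_fr3_log_parses_with_four_events(self):
        log = parse_session_log(LOG_TEXT)
        assert len(log.events) == 4
        assert log.fr_value == 3 and log.timeout_s == 20

    def test_empty_event_section_gives_zero_summary(self):
        head = LOG_TEXT.split("t_sec,kind")[0] + "t_sec,kind\n"
        log = parse_session_log(head)
        s = session_summary(log)
        assert (s.infusions, s.active, s.inactive) == (0, 0, 0)

    @pytest.mark.parametrize(
        "mutation,needle",
        [
            (lambda t: t.replace("12,infusion", "13,lever"), "lever"),
            (lambda t: t.replace("10,active", "999999,active"), "outside"),
            (lambda t: t.replace("# day=1", "# day=1\n# day=2"), "duplicate"),
            (lambda t: t.replace("10,active", "ten,active"), "timestamp"),
        ],
    )
    def test_malformed_input_raises_with_context(self, mutation, needle):
        with pytest.raises(SessionParseError, match=needle):
            parse_session_log(mutation(LOG_TEXT))

    def test_round_trip_preserves_log(self):
        log = parse_session_log(LOG_TEXT)
        buf = io.StringIO()
        write_session_log(log, buf)
        again = parse_session_log(buf.getvalue())
        assert again.subject_id == log.subject_id
        assert again.fr_value == log.fr_value
        assert [(round(t, 3), k) for t, k in log.events] == again.events


class TestScheduleSemantics:
    def test_hand_traced_fr1_session_is_clean(self):
        # active→infusion at 10 s; poke at 15 s inside timeout (no infusion);
        # poke at 35 s after expiry earns the next infusion
        log = SessionLog("S1", 1, events=[
            (10.0, "active"), (10.0, "infusion"),
            (15.0, "active"),
            (35.0, "active"), (35.0, "infusion"),
        ])
        assert validate_schedule_semantics(log) == []

    def test_infusion_inside_timeout_flagged(self):
        log = SessionLog("S1", 1, events=[
            (10.0, "active"), (10.0, "infusion"),
            (15.0, "active"), (15.0, "infusion"),
        ])
        v = validate_schedule_semantics(log)
        assert len(v) == 1 and "timeout" in v[0]

    def test_fr5_with_only_four_counted_actives_flagged(self):
        events = [(float(t), "active") for t in (1, 2, 3, 4)]
        events.append((5.0, "infusion"))
        log = SessionLog("S1", 1, events=events, fr_value=5)
        v = validate_schedule_semantics(log)
        assert len(v) == 1 and "4 counted" in v[0]


class TestSummaries:
    @pytest.mark.parametrize(
        "active,inactive,expected,defined",
        [(40, 10, 4.0, True), (12, 0, math.inf, True), (0, 0, None, False)],
    )
    def test_ratio_conventions(self, active, inactive, expected, defined):
        events = [(1.0 + i, "active") for i in range(active)]
        events += [(500.0 + i, "inactive") for i in range(inactive)]
        s = session_summary(SessionLog("S1", 1, events=events))
        assert s.ratio_defined is defined
        if expected is not None:
            assert s.ratio == expected

    def test_infusion_times_sorted_minutes(self):
        log = SessionLog("S1", 1, events=[(600.0, "infusion"), (60.0, "infusion")])
        np.testing.assert_allclose(infusion_times(log), [1.0, 10.0])
        assert infusion_times(SessionLog("S1", 1)).size == 0

    @pytest.mark.parametrize(
        "counts,expected",
        [([12, 11, 10, 12, 10], 11.0), ([11, 11, 11, 12, 11], 11.2), ([7], 7.0)],
    )
    def test_phase_mean_infusions(self, counts, expected):
        h = make_history([0] * 5 + counts)  # counts occupy days 6..10
        days = (6, 6 + len(counts) - 1)
        assert phase_mean_infusions(h, days) == pytest.approx(expected)

    def test_missing_day_raises_coverage_error(self):
        h = make_history([5, 5, 5])
        with pytest.raises(CoverageError):
            phase_mean_infusions(h, (1, 5))


class TestStandardDoseClassifier:
    def base_counts(self):
        return dict(
            infusions_per_day=[15] * 10,
            actives_per_day=[30] * 10,
            inactives_per_day=[2] * 10,
        )

    def test_healthy_history_acquires(self):
        out = classify_standard_dose(make_history(**self.base_counts()))
        assert out.verdict == "acquired" and out.triggered_rule is None

    def test_two_consecutive_low_infusion_sessions_fail_rule1(self):
        kw = self.base_counts()
        kw["infusions_per_day"] = [15, 15, 15, 15, 15, 9, 9, 15, 15, 15]
        out = classify_standard_dose(make_history(**kw))
        assert out.verdict == "failed" and out.triggered_rule == "rule1_low_infusions"

    def test_single_low_session_does_not_fail(self):
        kw = self.base_counts()
        kw["infusions_per_day"] = [15, 9, 15, 15, 15, 15, 15, 15, 15, 15]
        assert classify_standard_dose(make_history(**kw)).verdict == "acquired"

    def test_exactly_ten_infusions_is_not_low(self):
        kw = self.base_counts()
        kw["infusions_per_day"] = [10] * 10
        assert classify_standard_dose(make_history(**kw)).verdict == "acquired"

    def test_ratio_exactly_two_is_not_a_failure(self):
        kw = self.base_counts()
        kw["actives_per_day"] = [30] * 10
        kw["inactives_per_day"] = [15] * 10  # ratio exactly 2.0, strict < applies
        assert classify_standard_dose(make_history(**kw)).verdict == "acquired"

    def test_three_consecutive_low_ratio_sessions_fail_rule2(self):
        kw = self.base_counts()
        kw["inactives_per_day"] = [2, 2, 20, 20, 20, 2, 2, 2, 2, 2]  # ratio 1.5 × 3
        out = classify_standard_dose(make_history(**kw))
        assert out.triggered_rule == "rule2_low_ratio"

    def test_seventyfive_percent_drop_in_window_fails_rule3(self):
        kw = self.base_counts()
        kw["actives_per_day"] = [100, 100, 100, 100, 100, 25, 100, 100, 100, 100]
        kw["infusions_per_day"] = [20] * 10
        out = classify_standard_dose(make_history(**kw))
        assert out.triggered_rule == "rule3_response_drop"
        assert out.details["active_baseline"] == pytest.approx(100.0)

    def test_drop_smaller_than_seventyfive_percent_passes(self):
        kw = self.base_counts()
        kw["actives_per_day"] = [100, 100, 100, 100, 100, 26, 100, 100, 100, 100]
        kw["infusions_per_day"] = [20] * 10
        assert classify_standard_dose(make_history(**kw)).verdict == "acquired"

    def test_adding_infusions_never_converts_acquired_to_failed(self):
        # monotonicity of rule 1 in infusion counts
        kw = self.base_counts()
        kw["infusions_per_day"] = [11, 11, 11, 11, 11, 11, 11, 11, 11, 11]
        base = classify_standard_dose(make_history(**kw))
        kw["infusions_per_day"] = [n + 5 for n in kw["infusions_per_day"]]
        kw["actives_per_day"] = [a + 5 for a in kw["actives_per_day"]]
        more = classify_standard_dose(make_history(**kw))
        assert base.verdict == "acquired"
        assert more.verdict == "acquired"


class TestLowDoseClassifier:
    @pytest.mark.parametrize(
        "window_counts,verdict",
        [
            ([12, 11, 10, 12, 10], "failed"),  # mean 11.0 < 11.1
            ([11, 11, 11, 12, 11], "acquired"),  # mean 11.2
            ([5] * 5, "failed"),
            ([25] * 5, "acquired"),
        ],
    )
    def test_window_mean_against_cutoff(self, window_counts, verdict):
        h = make_history([15] * 5 + window_counts, dose_ug_per_kg=1.5)
        assert classify_low_dose(h).verdict == verdict

    def test_mean_exactly_at_cutoff_acquires(self):
        # 11.1 is "maintained": only strictly below fails
        crit = AcquisitionCriteria(lowdose_mean_cutoff=11.0)
        h = make_history([15] * 5 + [11] * 5, dose_ug_per_kg=1.5)
        assert classify_low_dose(h, crit).verdict == "acquired"


class TestControlReferenced:
    def controls(self, means):
        return [
            make_history([0] * 10 + [m] * 7, subject_id=f"C{i}")
            for i, m in enumerate(means)
        ]

    def test_zero_spread_controls_cutoff_is_their_mean(self):
        cutoff = control_referenced_cutoff(self.controls([4] * 6), (11, 17))
        assert cutoff == pytest.approx(4.0)

    def test_sample_sd_convention(self):
        cutoff = control_referenced_cutoff(self.controls([3, 3, 4, 4, 5, 5]), (11, 17))
        assert cutoff == pytest.approx(4 + 2 * np.std([3, 3, 4, 4, 5, 5], ddof=1))

    def test_single_control_raises(self):
        with pytest.raises(DegenerateSDError):
            control_referenced_cutoff(self.controls([4]), (11, 17))

    def test_subject_below_cutoff_fails(self):
        subj = make_history([0] * 10 + [5] * 7, subject_id="T1")
        out = classify_control_referenced(subj, 6.0, (11, 17))
        assert out.verdict == "failed" and out.triggered_rule == "below_control_cutoff"
        out2 = classify_control_referenced(
            make_history([0] * 10 + [7] * 7, subject_id="T2"), 6.0, (11, 17)
        )
        assert out2.verdict == "acquired"


class TestSubstitution:
    @pytest.mark.parametrize(
        "pre,post,expected",
        [
            ([20] * 5, [5] * 7, -15.0),
            ([8] * 5, [8] * 7, 0.0),
            ([18] * 5, [6] * 7, -12.0),
        ],
    )
    def test_paired_window_difference(self, pre, post, expected):
        h = make_history(pre + post)
        got = substitution_effect(h, (1, 5), (6, 12))
        assert got == pytest.approx(expected)


def test_outcome_invariant_failed_iff_rule():
    with pytest.raises(ValueError):
        AcquisitionOutcome("S", "failed", None)
    with pytest.raises(ValueError):
        AcquisitionOutcome("S", "acquired", "rule1")


def test_classifiers_independent_of_subject_order():
    hists = [
        make_history([15] * 10, subject_id=f"S{i}", dose_ug_per_kg=1.5)
        for i in range(4)
    ] + [make_history([3] * 10, subject_id="S9", dose_ug_per_kg=1.5)]
    fwd = [classify_low_dose(h).verdict for h in hists]
    rev = [classify_low_dose(h).verdict for h in reversed(hists)]
    assert fwd == list(reversed(rev))
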