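"""Session scoring against reference sequences, cohort aggregation, and the
automatic report."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from traumasim import (
    EventLog,
    SessionEvent,
    SessionMetrics,
    TerminalRecord,
    cohort_metrics,
    enumerate_sequences,
    generate_report,
    mandatory,
    optional,
    alternative,
    parse_report,
    repeatable,
    score_session,
)
from traumasim.session_scoring import format_proportion, round_half_up

from conftest import make_model


def make_log(actions, group="student", trainee="t0", outcome="alive",
             end_time=None):
    events = [
        SessionEvent(action_id=a, time=float(i), vitals_before={},
                     vitals_after={})
        for i, a in enumerate(actions)
    ]
    if end_time is None:
        end_time = float(len(actions))
    return EventLog(
        log_id=f"log:{trainee}", scenario_id="pelvic_default",
        trainee_id=trainee, group=group, events=events,
        terminal=TerminalRecord(outcome=outcome, end_time=end_time),
    )


def is_subsequence(sub, seq):
    it = iter(seq)
    return all(x in it for x in sub)


def oracle_scores(log_actions, references):
    """Exhaustive oracle: best subsequence / best contiguous block."""
    n = len(log_actions)
    best_sub = 0
    for r in range(n, 0, -1):
        if any(
            is_subsequence(cand, ref)
            for cand in itertools.combinations(log_actions, r)
            for ref in references
        ):
            best_sub = r
            break
    best_block = 0
    for i in range(n):
        for j in range(i + 1, n + 1):
            block = tuple(log_actions[i:j])
            for ref in references:
                if any(
                    tuple(ref[k:k + len(block)]) == block
                    for k in range(len(ref) - len(block) + 1)
                ):
                    best_block = max(best_block, j - i)
    return best_sub, best_block


class TestScoreSession:
    def test_perfect_reference_log(self, model):
        ref = enumerate_sequences(model)[0]
        m = score_session(make_log(ref), model)
        assert (m.n_actions, m.n_correct, m.n_sequential) == (
            len(ref), len(ref), len(ref)
        )

    def test_empty_log_scores_zero(self, model):
        m = score_session(make_log([]), model)
        assert (m.n_actions, m.n_correct, m.n_sequential) == (0, 0, 0)
        assert all(t is None for t in m.per_action.values())

    def test_first_occurrence_times_extracted(self, model):
        log = make_log(["oxygenation", "airway_inspection", "oxygenation"])
        m = score_session(log, model)
        assert m.per_action["oxygenation"] == 0.0
        assert m.per_action["airway_inspection"] == 1.0
        assert m.per_action["pelvic_binder"] is None

    def test_agrees_with_exhaustive_oracle_on_toy_model(self):
        toy = make_model(
            [mandatory("a"), alternative("b", "c"), optional("d"),
             repeatable("e", 1)],
            "a", "b", "c", "d", "e",
        )
        refs = enumerate_sequences(toy)
        rng = np.random.default_rng(7)
        vocab = ["a", "b", "c", "d", "e", "x"]
        for _ in range(60):
            n = int(rng.integers(0, 7))
            actions = [vocab[i] for i in rng.integers(0, len(vocab), n)]
            m = score_session(make_log(actions), toy)
            exp_correct, exp_seq = oracle_scores(actions, refs)
            assert m.n_correct == exp_correct
            assert m.n_sequential == exp_seq

    def test_agrees_with_oracle_on_default_model_short_logs(self, model):
        refs = enumerate_sequences(model)
        rng = np.random.default_rng(11)
        vocab = sorted({a for ref in refs for a in ref})
        for _ in range(15):
            n = int(rng.integers(0, 9))
            actions = [vocab[i] for i in rng.integers(0, len(vocab), n)]
            m = score_session(make_log(actions), model)
            exp_correct, exp_seq = oracle_scores(actions, refs)
            assert (m.n_correct, m.n_sequential) == (exp_correct, exp_seq)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(actions=st.lists(
        st.sampled_from([
            "airway_inspection", "oxygenation", "pelvic_binder",
            "crystalloids", "blood_transfusion", "thermal_blanket",
            "bogus_action",
        ]),
        max_size=15,
    ))
    def test_metric_ordering_invariant(self, actions, model):
        m = score_session(make_log(actions), model)
        assert m.n_sequential <= m.n_correct <= m.n_actions


TABLE_COUNTS = {  # action -> (students performing of 28, doctors of 13)
    "airway_inspection": (20, 11),
    "oxygenation": (27, 13),
    "intubation": (19, 7),
    "pelvic_binder": (20, 10),
    "blood_transfusion": (24, 12),
    "crystalloids": (20, 11),
    "thermal_blanket": (12, 2),
    "hot_liquids": (6, 8),
}

EXPECTED_PERCENT = {
    "airway_inspection": ("71% (20/28)", "85% (11/13)"),
    "oxygenation": ("96% (27/28)", "100% (13/13)"),
    "intubation": ("68% (19/28)", "54% (7/13)"),
    "pelvic_binder": ("71% (20/28)", "77% (10/13)"),
    "blood_transfusion": ("86% (24/28)", "92% (12/13)"),
    "crystalloids": ("71% (20/28)", "85% (11/13)"),
    "thermal_blanket": ("43% (12/28)", "15% (2/13)"),
    "hot_liquids": ("21% (6/28)", "62% (8/13)"),
    "warming_measures": ("64% (18/28)", "77% (10/13)"),
}


def fixture_cohort():
    """Deterministic cohort whose per-action counts equal the pilot-study
    tallies; warming measures are disjoint across trainees, so the union
    count is the sum of the two counts."""
    logs = []
    for group, size in (("student", 28), ("doctor", 13)):
        for i in range(size):
            actions = [
                action for action, counts in TABLE_COUNTS.items()
                if action != "hot_liquids"
                and i < counts[0 if group == "student" else 1]
            ]
            k_thermal = TABLE_COUNTS["thermal_blanket"][group == "doctor"]
            k_hot = TABLE_COUNTS["hot_liquids"][group == "doctor"]
            if k_thermal <= i < k_thermal + k_hot:
                actions.append("hot_liquids")
            logs.append(make_log(actions, group=group, trainee=f"{group}{i}"))
    return logs


class TestCohortMetrics:
    def test_reproduces_every_pilot_percentage(self, model):
        summary = cohort_metrics(fixture_cohort(), model)
        for action, (student, doctor) in EXPECTED_PERCENT.items():
            assert summary.action_counts[action]["student"].formatted == student
            assert summary.action_counts[action]["doctor"].formatted == doctor

    def test_half_up_percentage_rounding(self):
        assert round_half_up(70.5) == 71
        assert round_half_up(84.6) == 85
        assert format_proportion(20, 28) == "71% (20/28)"
        assert format_proportion(1, 8) == "13% (1/8)"  # 12.5 rounds up

    def test_mean_sd_on_hand_computed_fixture(self, model):
        logs = [
            make_log(actions, trainee=f"t{i}", end_time=end)
            for i, (actions, end) in enumerate([
                (["airway_inspection"], 10.0),
                (["airway_inspection", "oxygenation"], 20.0),
                ([], 30.0),
                (["oxygenation"] * 3, 40.0),
                (["pelvic_binder"] * 2, 50.0),
            ])
        ]
        summary = cohort_metrics(logs, model)
        tt = summary.metrics["treatment_time"]["student"]
        assert tt.mean == pytest.approx(30.0)
        assert tt.sd == pytest.approx(np.std([10, 20, 30, 40, 50], ddof=1))
        na = summary.metrics["n_actions"]["student"]
        assert na.mean == pytest.approx(np.mean([1, 2, 0, 3, 2]))
        assert na.sd == pytest.approx(np.std([1, 2, 0, 3, 2], ddof=1))

    def test_single_log_group_flagged_degenerate(self, model):
        summary = cohort_metrics([make_log(["oxygenation"])], model)
        m = summary.metrics["n_actions"]["student"]
        assert m.sd == 0.0
        assert m.degenerate

    def test_empty_cohort_rejected(self, model):
        with pytest.raises(ValueError, match="empty cohort"):
            cohort_metrics([], model)


class TestReport:
    def test_report_lists_every_event_and_round_trips(self, model):
        log = make_log(["airway_inspection", "oxygenation", "pelvic_binder"])
        metrics = score_session(log, model)
        doc = generate_report(log, metrics)
        assert doc["markdown"].count("| airway_inspection |") == 1
        log2, metrics2 = parse_report(doc["json"])
        assert log2 == log
        assert metrics2 == metrics

    def test_report_deterministic(self, model):
        log = make_log(["airway_inspection"])
        metrics = score_session(log, model)
        assert generate_report(log, metrics) == generate_report(log, metrics)

    def test_mismatched_metrics_rejected(self, model):
        log = make_log(["airway_inspection"])
        metrics = score_session(log, model).model_copy(
            update={"log_id": "someone_else"}
        )
        with pytest.raises(ValueError, match="does not match"):
            generate_report(log, metrics)


def test_metric_ordering_enforced_by_schema():
    with pytest.raises(ValueError, match="ordering"):
        SessionMetrics(
            log_id="x", treatment_time=1.0, n_actions=2, n_correct=3,
            n_sequential=1, per_action={},
        )
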