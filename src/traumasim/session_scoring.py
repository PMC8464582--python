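"""Session event logs, performance metrics and post-session reports.

A session produces an :class:`EventLog`: every action taken, with the vitals
immediately before and after, plus a terminal record (patient alive at
session end, or time of death).  Scoring compares the logged action sequence
against the ATLS reference set:

* ``n_correct``    — the best longest-common-subsequence (LCS) length
  between the log and any reference sequence: actions performed in the
  right relative order, allowing interspersed extras;
* ``n_sequential`` — the longest contiguous run of logged actions that also
  appears contiguously in some reference sequence: uninterrupted adherence.

Cohort summaries aggregate per-group means +/- SD of the numeric metrics and
per-action performance percentages formatted "p% (k/n)" with half-up integer
rounding, the convention used in clinical reporting.
"""

from __future__ import annotations

import io
import json
import math
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .atls_reference import ReferenceModel, enumerate_sequences
from .scenario_model import VITAL_NAMES


class TraineeGroup(str, Enum):
    student = "student"
    doctor = "doctor"


class SessionEvent(BaseModel):
    action_id: str
    time: float = Field(ge=0)  # minutes since patient arrival
    vitals_before: dict[str, float]
    vitals_after: dict[str, float]


class TerminalRecord(BaseModel):
    outcome: str  # "alive" | "dead"
    end_time: float = Field(ge=0)

    @model_validator(mode="after")
    def _known_outcome(self) -> "TerminalRecord":
        if self.outcome not in ("alive", "dead"):
            raise ValueError(f"outcome must be 'alive' or 'dead', got {self.outcome!r}")
        return self


class EventLog(BaseModel):
    log_id: str
    scenario_id: str
    trainee_id: str
    group: TraineeGroup
    events: list[SessionEvent] = Field(default_factory=list)
    terminal: TerminalRecord

    @model_validator(mode="after")
    def _times_consistent(self) -> "EventLog":
        times = [e.time for e in self.events]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event times must be non-decreasing")
        if times and self.terminal.end_time < times[-1]:
            raise ValueError("terminal end_time precedes last event")
        return self

    def action_sequence(self) -> tuple[str, ...]:
        return tuple(e.action_id for e in self.events)


# --------------------------------------------------------------------------
# JSONL persistence: one header record, one record per event, one terminal
# record, one JSON object per line.
# --------------------------------------------------------------------------

def write_event_log(log: EventLog, path_or_buf) -> None:
    own = isinstance(path_or_buf, (str, bytes)) or hasattr(path_or_buf, "__fspath__")
    fh = open(path_or_buf, "w") if own else path_or_buf
    try:
        header = {
            "record": "header", "log_id": log.log_id,
            "scenario_id": log.scenario_id, "trainee_id": log.trainee_id,
            "group": log.group.value,
        }
        fh.write(json.dumps(header, sort_keys=True) + "\n")
        for ev in log.events:
            rec = {"record": "event", **ev.model_dump()}
            fh.write(json.dumps(rec, sort_keys=True) + "\n")
        fh.write(json.dumps(
            {"record": "terminal", **log.terminal.model_dump()}, sort_keys=True
        ) + "\n")
    finally:
        if own:
            fh.close()


def read_event_log(path_or_buf) -> EventLog:
    own = isinstance(path_or_buf, (str, bytes)) or hasattr(path_or_buf, "__fspath__")
    fh = open(path_or_buf) if own else path_or_buf
    try:
        records = [json.loads(line) for line in fh if line.strip()]
    finally:
        if own:
            fh.close()
    if not records or records[0].get("record") != "header":
        raise ValueError("event log must start with a header record")
    header = records[0]
    events, terminal = [], None
    for rec in records[1:]:
        kind = rec.pop("record", None)
        if kind == "event":
            events.append(SessionEvent(**rec))
        elif kind == "terminal":
            terminal = TerminalRecord(**rec)
        else:
            raise ValueError(f"unknown record type {kind!r}")
    if terminal is None:
        raise ValueError("event log missing terminal record")
    return EventLog(
        log_id=header["log_id"], scenario_id=header["scenario_id"],
        trainee_id=header["trainee_id"], group=header["group"],
        events=events, terminal=terminal,
    )


# --------------------------------------------------------------------------
# Per-session metrics
# --------------------------------------------------------------------------

class SessionMetrics(BaseModel):
    log_id: str
    treatment_time: float = Field(ge=0)
    n_actions: int = Field(ge=0)
    n_correct: int = Field(ge=0)
    n_sequential: int = Field(ge=0)
    per_action: dict[str, Optional[float]]  # first occurrence time, or None

    @model_validator(mode="after")
    def _ordering(self) -> "SessionMetrics":
        if not self.n_sequential <= self.n_correct <= self.n_actions:
            raise ValueError(
                "metric ordering violated: n_sequential <= n_correct <= n_actions"
            )
        return self


def _lcs_length(a: Sequence[str], b: Sequence[str]) -> int:
    """Longest common subsequence length by dynamic programming."""
    if not a or not b:
        return 0
    prev = [0] * (len(b) + 1)
    for x in a:
        curr = [0]
        for j, y in enumerate(b, 1):
            curr.append(prev[j - 1] + 1 if x == y else max(prev[j], curr[j - 1]))
        prev = curr
    return prev[-1]


def _longest_common_substring(a: Sequence[str], b: Sequence[str]) -> int:
    """Longest contiguous block shared by ``a`` and ``b``."""
    best = 0
    prev = [0] * (len(b) + 1)
    for x in a:
        curr = [0] * (len(b) + 1)
        for j, y in enumerate(b, 1):
            if x == y:
                curr[j] = prev[j - 1] + 1
                best = max(best, curr[j])
        prev = curr
    return best


def score_session(log: EventLog, model: ReferenceModel) -> SessionMetrics:
    """Score one session against the reference model.

    A valid log with no events scores zero on every count.
    """
    references = enumerate_sequences(model)
    seq = log.action_sequence()
    n_correct = max((_lcs_length(seq, ref) for ref in references), default=0)
    n_sequential = max(
        (_longest_common_substring(seq, ref) for ref in references), default=0
    )
    first_times: dict[str, Optional[float]] = {
        a.action_id: None for a in model.catalog
    }
    for ev in log.events:
        if first_times.get(ev.action_id) is None:
            first_times[ev.action_id] = ev.time
    return SessionMetrics(
        log_id=log.log_id,
        treatment_time=log.terminal.end_time,
        n_actions=len(seq),
        n_correct=n_correct,
        n_sequential=n_sequential,
        per_action=first_times,
    )


# --------------------------------------------------------------------------
# Cohort summary
# --------------------------------------------------------------------------

NUMERIC_METRICS = ("treatment_time", "n_actions", "n_correct", "n_sequential")

#: Actions counted as one combined "warming measures" row; in practice a
#: trainee applies one or the other, so the union percentage is the sum of
#: the two marginals.
DEFAULT_UNION_ROWS = {"warming_measures": ("thermal_blanket", "hot_liquids")}


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def format_proportion(k: int, n: int) -> str:
    return f"{round_half_up(100.0 * k / n)}% ({k}/{n})"


class GroupActionCount(BaseModel):
    performed: int
    group_size: int
    percentage: int
    formatted: str


class GroupMetricSummary(BaseModel):
    mean: float
    sd: float
    n: int
    degenerate: bool = False  # single-session group: SD reported as 0


class CohortSummary(BaseModel):
    group_sizes: dict[str, int]
    metrics: dict[str, dict[str, GroupMetricSummary]]      # metric -> group
    action_counts: dict[str, dict[str, GroupActionCount]]  # action -> group


def cohort_metrics(
    logs: Iterable[EventLog],
    model: ReferenceModel,
    union_rows: dict[str, tuple[str, ...]] | None = None,
) -> CohortSummary:
    """Aggregate scored sessions into the per-group summary table.

    Numeric metrics are reported mean +/- sample SD (n-1 denominator);
    per-action rows as half-up rounded percentages with raw counts.
    """
    logs = list(logs)
    if not logs:
        raise ValueError("empty cohort")
    if union_rows is None:
        union_rows = {k: v for k, v in DEFAULT_UNION_ROWS.items()}

    by_group: dict[str, list[EventLog]] = {}
    for log in logs:
        by_group.setdefault(log.group.value, []).append(log)

    scored = {
        g: [score_session(log, model) for log in group_logs]
        for g, group_logs in by_group.items()
    }

    metrics: dict[str, dict[str, GroupMetricSummary]] = {}
    for metric in NUMERIC_METRICS:
        metrics[metric] = {}
        for g, ms in scored.items():
            values = np.array([getattr(m, metric) for m in ms], dtype=float)
            degenerate = len(values) < 2
            sd = 0.0 if degenerate else float(np.std(values, ddof=1))
            metrics[metric][g] = GroupMetricSummary(
                mean=float(values.mean()), sd=sd, n=len(values),
                degenerate=degenerate,
            )

    action_ids = [a.action_id for a in model.catalog]
    action_counts: dict[str, dict[str, GroupActionCount]] = {}
    for action_id in action_ids:
        action_counts[action_id] = {}
        for g, group_logs in by_group.items():
            n = len(group_logs)
            k = sum(
                1 for log in group_logs
                if action_id in set(log.action_sequence())
            )
            action_counts[action_id][g] = GroupActionCount(
                performed=k, group_size=n,
                percentage=round_half_up(100.0 * k / n),
                formatted=format_proportion(k, n),
            )
    for row_name, members in union_rows.items():
        action_counts[row_name] = {}
        for g, group_logs in by_group.items():
            n = len(group_logs)
            k = sum(
                1 for log in group_logs
                if set(log.action_sequence()) & set(members)
            )
            action_counts[row_name][g] = GroupActionCount(
                performed=k, group_size=n,
                percentage=round_half_up(100.0 * k / n),
                formatted=format_proportion(k, n),
            )

    return CohortSummary(
        group_sizes={g: len(v) for g, v in by_group.items()},
        metrics=metrics,
        action_counts=action_counts,
    )


# --------------------------------------------------------------------------
# Automatic post-session report
# --------------------------------------------------------------------------

def generate_report(log: EventLog, metrics: SessionMetrics) -> dict[str, str]:
    """Render the automatic post-session report.

    Returns ``{"json": ..., "markdown": ...}``; the JSON document is
    canonical (sorted keys) and round-trips through :func:`parse_report`.
    """
    if metrics.log_id != log.log_id:
        raise ValueError(
            f"metrics log_id {metrics.log_id!r} does not match log {log.log_id!r}"
        )
    doc = {
        "log_id": log.log_id,
        "scenario_id": log.scenario_id,
        "trainee_id": log.trainee_id,
        "group": log.group.value,
        "events": [ev.model_dump() for ev in log.events],
        "terminal": log.terminal.model_dump(),
        "metrics": metrics.model_dump(),
    }
    json_text = json.dumps(doc, sort_keys=True, indent=2)

    buf = io.StringIO()
    buf.write(f"# Session report — {log.log_id}\n\n")
    buf.write(f"Scenario: {log.scenario_id}  \n")
    buf.write(f"Trainee: {log.trainee_id} ({log.group.value})\n\n")
    buf.write("## Timeline\n\n")
    buf.write("| t (min) | action | " +
              " | ".join(f"{v} before/after" for v in VITAL_NAMES) + " |\n")
    buf.write("|---" * (2 + len(VITAL_NAMES)) + "|\n")
    for ev in log.events:
        cells = [
            f"{ev.vitals_before.get(v, float('nan')):.1f} / "
            f"{ev.vitals_after.get(v, float('nan')):.1f}"
            for v in VITAL_NAMES
        ]
        buf.write(f"| {ev.time:g} | {ev.action_id} | " + " | ".join(cells) + " |\n")
    buf.write(
        f"\n**Outcome:** patient {log.terminal.outcome} at "
        f"t = {log.terminal.end_time:g} min.\n\n"
    )
    buf.write("## Metrics\n\n")
    buf.write(f"- Treatment time: {metrics.treatment_time:g} min\n")
    buf.write(f"- Actions performed: {metrics.n_actions}\n")
    buf.write(f"- Correct actions (best reference LCS): {metrics.n_correct}\n")
    buf.write(f"- Sequential actions (longest reference block): "
              f"{metrics.n_sequential}\n")
    return {"json": json_text, "markdown": buf.getvalue()}


def parse_report(json_text: str) -> tuple[EventLog, SessionMetrics]:
    """Re-parse a machine-readable report back into its log and metrics."""
    doc = json.loads(json_text)
    log = EventLog(
        log_id=doc["log_id"], scenario_id=doc["scenario_id"],
        trainee_id=doc["trainee_id"], group=doc["group"],
        events=[SessionEvent(**e) for e in doc["events"]],
        terminal=TerminalRecord(**doc["terminal"]),
    )
    return log, SessionMetrics(**doc["metrics"])
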