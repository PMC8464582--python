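"""Discrete-time virtual-patient dynamics.

The patient deteriorates toward death when untreated and responds to the
trainee's actions.  The paper-facing contract is the remaining-lifetime
calibration: absent any action, the first lethal-bound crossing occurs at
the scenario's ``remaining_lifetime`` (within one tick).

Model
-----
The lethal mechanism of the pelvic scenario is hemorrhage.  Blood volume
(fraction of normal) falls linearly at ``bleeding_rate``; the circulatory
vitals are driven by volume loss through linear couplings

    systolic_bp  = sbp0 - k_sbp * (1 - volume)
    diastolic_bp = dbp0 - k_dbp * (1 - volume)
    heart_rate   = hr0  + k_hr  * (1 - volume)

and ``bleeding_rate`` is calibrated per scenario so systolic pressure
reaches its lethal bound exactly at ``remaining_lifetime``.  The remaining
vitals (SpO2, respiratory rate, temperature, consciousness) deteriorate
along independent linear slopes calibrated to cross their lethal bound at
``deterioration_slack`` times the remaining lifetime, so the hemorrhage is
always the proximate cause of an untreated death.

Actions apply additive deltas (with physiological clipping) and register
multiplicative slope modifiers.  A pelvic binder multiplies the bleeding
rate by ``binder_bleeding_factor``; fluids add volume at full efficiency
only once bleeding is controlled — while the hemorrhage is uncontrolled
most of the infused volume is lost through it.  Controlling the hemorrhage
also arrests the secondary (shock-driven) deterioration of the independent
vitals via ``controlled_deterioration_factor``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from pydantic import BaseModel, Field

from .scenario_model import (
    PHYSIOLOGIC_RANGES,
    ActionDefinition,
    TraumaScenario,
    get_catalog,
)
from .session_scoring import (
    EventLog,
    SessionEvent,
    TerminalRecord,
    TraineeGroup,
)

#: Vitals computed from blood volume each tick rather than integrated.
COUPLED_VITALS = ("heart_rate", "systolic_bp", "diastolic_bp")
#: Vitals integrated along their own deterioration slope.
INDEPENDENT_VITALS = ("spo2", "respiratory_rate", "temperature", "consciousness")

#: Direction each independent vital drifts when the patient deteriorates:
#: -1 toward its lower lethal bound, +1 toward the upper one.
_DETERIORATION_DIRECTION = {
    "spo2": -1,
    "respiratory_rate": +1,  # shock tachypnea
    "temperature": -1,
    "consciousness": -1,
}

BLOOD_VOLUME_CAP = 1.2


class EngineConfig(BaseModel):
    """Tunable constants of the patient model (time unit: minutes)."""

    tick: int = Field(default=1, gt=0)
    horizon: int = Field(default=480, gt=0)
    #: bleeding-rate multiplier once a pelvic binder is placed
    binder_bleeding_factor: float = Field(default=0.1, ge=0, le=1)
    #: fraction of infused volume retained while bleeding is uncontrolled
    uncontrolled_fluid_efficiency: float = Field(default=0.2, ge=0, le=1)
    #: bleeding counts as controlled at or below this fraction of the
    #: scenario's calibrated untreated rate
    controlled_threshold_fraction: float = Field(default=0.25, ge=0, le=1)
    #: independent-vital slopes are scaled by this once bleeding is
    #: controlled (0 = controlling the hemorrhage halts secondary decline)
    controlled_deterioration_factor: float = Field(default=0.0, ge=0, le=1)
    #: untreated independent vitals cross their lethal bound at
    #: slack * remaining_lifetime, keeping hemorrhage the first cause
    deterioration_slack: float = Field(default=1.5, gt=1)
    # linear hemorrhage couplings (units per unit volume fraction lost)
    sbp_sensitivity: float = Field(default=120.0, gt=0)
    dbp_sensitivity: float = Field(default=60.0, ge=0)
    hr_sensitivity: float = Field(default=60.0, ge=0)


class DeadPatientError(RuntimeError):
    """An operation was attempted on a dead (absorbing-state) patient."""


class ActionError(ValueError):
    """Unknown action, unmet prerequisite, or repetition limit exceeded."""


@dataclass
class SimulationState:
    time: int
    vitals: dict[str, float]
    blood_volume: float
    bleeding_rate: float
    alive: bool
    baseline: dict[str, float]              # arrival vitals (coupling anchors)
    untreated_bleeding_rate: float
    slopes: dict[str, float]                # per independent vital, units/min
    slope_factors: dict[str, float] = field(
        default_factory=lambda: {v: 1.0 for v in INDEPENDENT_VITALS}
    )
    coupled_offsets: dict[str, float] = field(
        default_factory=lambda: {v: 0.0 for v in COUPLED_VITALS}
    )
    action_counts: dict[str, int] = field(default_factory=dict)
    performed: set[str] = field(default_factory=set)
    catalog_ids: frozenset[str] = frozenset()
    lethal_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    death_time: Optional[int] = None

    def bleeding_controlled(self, config: EngineConfig) -> bool:
        threshold = (
            config.controlled_threshold_fraction * self.untreated_bleeding_rate
        )
        return self.bleeding_rate <= threshold


def _clip(vital: str, value: float) -> float:
    lo, hi = PHYSIOLOGIC_RANGES[vital]
    return min(max(value, lo), hi)


def _coupled_value(state: SimulationState, config: EngineConfig, vital: str) -> float:
    deficit = 1.0 - state.blood_volume
    base = state.baseline[vital]
    if vital == "systolic_bp":
        v = base - config.sbp_sensitivity * deficit
    elif vital == "diastolic_bp":
        v = base - config.dbp_sensitivity * deficit
    else:  # heart_rate rises as volume is lost
        v = base + config.hr_sensitivity * deficit
    return _clip(vital, v + state.coupled_offsets[vital])


def _refresh_coupled(state: SimulationState, config: EngineConfig) -> None:
    for vital in COUPLED_VITALS:
        state.vitals[vital] = _coupled_value(state, config, vital)


def _check_alive(state: SimulationState) -> None:
    for vital, (lo, hi) in state.lethal_bounds.items():
        v = state.vitals[vital]
        if v < lo or v > hi:
            state.alive = False
            state.death_time = state.time
            return


def initialize(scenario: TraumaScenario, config: EngineConfig) -> SimulationState:
    """Build the t=0 state with slopes calibrated to the remaining lifetime.

    The bleeding rate is chosen so untreated systolic pressure reaches its
    lethal bound exactly at ``scenario.remaining_lifetime``; the other
    vitals are calibrated to cross later (see module docstring).
    """
    vitals = scenario.initial_vitals.as_dict()
    bounds = scenario.lethal_bounds.bounds
    violations = scenario.lethal_bounds.violations(vitals)
    if violations:
        raise ValueError(
            "patient dead on arrival: " + "; ".join(violations)
        )
    lifetime = scenario.remaining_lifetime
    sbp_low = bounds["systolic_bp"][0]
    sbp_margin = vitals["systolic_bp"] - sbp_low
    if sbp_margin <= 0:
        raise ValueError("initial systolic_bp at or below its lethal bound")
    bleeding_rate = sbp_margin / (config.sbp_sensitivity * lifetime)

    slopes: dict[str, float] = {}
    crossing_time = config.deterioration_slack * lifetime
    for vital in INDEPENDENT_VITALS:
        lo, hi = bounds.get(vital, PHYSIOLOGIC_RANGES[vital])
        target = lo if _DETERIORATION_DIRECTION[vital] < 0 else hi
        slopes[vital] = (target - vitals[vital]) / crossing_time

    catalog = get_catalog(scenario.catalog_id)
    return SimulationState(
        time=0,
        vitals=dict(vitals),
        blood_volume=1.0,
        bleeding_rate=bleeding_rate,
        alive=True,
        baseline=dict(vitals),
        untreated_bleeding_rate=bleeding_rate,
        slopes=slopes,
        catalog_ids=frozenset(a.action_id for a in catalog),
        lethal_bounds={k: tuple(v) for k, v in bounds.items()},
    )


def step(state: SimulationState, config: EngineConfig) -> SimulationState:
    """Advance the state by one tick (mutates and returns ``state``)."""
    if not state.alive:
        raise DeadPatientError(f"cannot step: patient died at t={state.death_time}")
    dt = config.tick
    state.time += dt
    shock_factor = (
        config.controlled_deterioration_factor
        if state.bleeding_controlled(config) else 1.0
    )
    for vital in INDEPENDENT_VITALS:
        rate = state.slopes[vital] * state.slope_factors[vital] * shock_factor
        state.vitals[vital] = _clip(vital, state.vitals[vital] + rate * dt)
    state.blood_volume = max(0.0, state.blood_volume - state.bleeding_rate * dt)
    _refresh_coupled(state, config)
    _check_alive(state)
    return state


def apply_action(
    state: SimulationState,
    action: ActionDefinition,
    config: EngineConfig,
) -> tuple[SimulationState, SessionEvent]:
    """Apply one action's effects; returns the state and an effect record
    capturing the vitals immediately before and after."""
    if not state.alive:
        raise DeadPatientError(
            f"cannot act: patient died at t={state.death_time}"
        )
    if action.action_id not in state.catalog_ids:
        raise ActionError(f"unknown action_id {action.action_id!r}")
    count = state.action_counts.get(action.action_id, 0)
    if count >= action.repeatable:
        raise ActionError(
            f"{action.action_id!r} already performed its maximum of "
            f"{action.repeatable} time(s)"
        )
    missing = set(action.prerequisites) - state.performed
    if missing:
        raise ActionError(
            f"{action.action_id!r} requires {sorted(missing)} first"
        )

    vitals_before = dict(state.vitals)
    for effect in action.effects:
        if effect.target == "bleeding_rate":
            factor = (
                effect.slope_factor
                if effect.slope_factor is not None
                else config.binder_bleeding_factor
            )
            state.bleeding_rate = max(
                0.0, state.bleeding_rate * factor + effect.delta
            )
        elif effect.target == "blood_volume":
            efficiency = (
                1.0 if state.bleeding_controlled(config)
                else config.uncontrolled_fluid_efficiency
            )
            gain = effect.delta * efficiency if effect.delta > 0 else effect.delta
            state.blood_volume = min(
                BLOOD_VOLUME_CAP, max(0.0, state.blood_volume + gain)
            )
        else:
            state.vitals[effect.target] = _clip(
                effect.target, state.vitals[effect.target] + effect.delta
            )
            if (
                effect.slope_factor is not None
                and effect.target in INDEPENDENT_VITALS
            ):
                state.slope_factors[effect.target] *= effect.slope_factor
    _refresh_coupled(state, config)
    state.action_counts[action.action_id] = count + 1
    state.performed.add(action.action_id)
    _check_alive(state)
    record = SessionEvent(
        action_id=action.action_id,
        time=float(state.time),
        vitals_before=vitals_before,
        vitals_after=dict(state.vitals),
    )
    return state, record


class ScriptError(ValueError):
    """Malformed action script."""


def _normalize_script(
    script: Sequence[tuple[str, float]],
    config: EngineConfig,
    catalog_ids: frozenset[str],
) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    prev = -math.inf
    for entry in script:
        try:
            action_id, t = entry
            t = float(t)
        except (TypeError, ValueError) as exc:
            raise ScriptError(f"malformed script entry {entry!r}") from exc
        if action_id not in catalog_ids:
            raise ScriptError(f"unknown action_id {action_id!r} in script")
        if not math.isfinite(t) or t < 0:
            raise ScriptError(f"invalid time {t!r} for {action_id!r}")
        if t < prev:
            raise ScriptError("script times must be non-decreasing")
        if t > config.horizon:
            raise ScriptError(
                f"script time {t} beyond horizon {config.horizon}"
            )
        prev = t
        out.append((action_id, int(math.floor(t + 0.5))))
    return out


def run_session(
    scenario: TraumaScenario,
    script: Sequence[tuple[str, float]],
    config: EngineConfig,
    *,
    trainee_id: str = "trainee",
    group: TraineeGroup | str = TraineeGroup.student,
    log_id: Optional[str] = None,
    session_end: Optional[int] = None,
) -> EventLog:
    """Deterministically replay a scripted session.

    Scheduled actions are applied at their (whole-minute) timestamps, before
    the deterioration tick at the same timestamp.  The session ends at the
    patient's death, at the last scheduled action (its natural end), or at
    ``session_end`` if given; an empty script with no ``session_end`` runs
    to death or the horizon.  Identical inputs produce identical logs.
    """
    catalog = {a.action_id: a for a in get_catalog(scenario.catalog_id)}
    norm = _normalize_script(script, config, frozenset(catalog))
    if session_end is not None:
        if session_end > config.horizon:
            raise ScriptError(
                f"session_end {session_end} beyond horizon {config.horizon}"
            )
        if norm and session_end < norm[-1][1]:
            raise ScriptError("session_end precedes the last scheduled action")

    state = initialize(scenario, config)
    events: list[SessionEvent] = []

    if session_end is not None:
        stop_time = session_end
    elif norm:
        stop_time = norm[-1][1]
    else:
        stop_time = config.horizon

    idx = 0
    while True:
        while idx < len(norm) and norm[idx][1] == state.time and state.alive:
            state, record = apply_action(state, catalog[norm[idx][0]], config)
            events.append(record)
            idx += 1
        if not state.alive or state.time >= stop_time:
            break
        step(state, config)

    if state.alive:
        terminal = TerminalRecord(outcome="alive", end_time=float(state.time))
    else:
        terminal = TerminalRecord(outcome="dead", end_time=float(state.death_time))
    return EventLog(
        log_id=log_id or f"{scenario.scenario_id}:{trainee_id}",
        scenario_id=scenario.scenario_id,
        trainee_id=trainee_id,
        group=TraineeGroup(group),
        events=events,
        terminal=terminal,
    )
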