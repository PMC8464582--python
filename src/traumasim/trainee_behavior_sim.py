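"""Synthetic trainee cohorts.

Human sessions are emulated by sampling action scripts from group-specific
behavioral profiles: per-action performance probabilities (how likely the
trainee is to perform the action at all), log-normal timing distributions,
and an adherence parameter governing how faithfully the trainee follows the
ATLS reference order.  The default profiles encode the observed per-action
performance fractions of a 28-student / 13-doctor pilot cohort.

Sampling semantics
------------------
Each synthetic trainee first realizes a reference sequence by walking the
grammar: alternative slots pick one member (uniformly, or proportionally
within a mutually exclusive pair) and repeatable slots a uniform repetition
count; whether an action is performed at all is decided once per slot with
the profile's probability for the realized action, so the marginal
performance probability of every mandatory, optional, repeatable and
mutually exclusive action equals its profile value exactly (a
non-exclusive alternative member recovers its value divided by the number
of alternatives, since the trainee commits to one route).  Thermal blanket
and hot liquids are the built-in mutually exclusive pair: the union event
fires with the sum of the two marginals and one measure is then chosen
proportionally, reproducing both marginals while never producing both.
The performed actions are ordered step-wise: at each step the trainee
follows the reference order with probability ``adherence``, otherwise
picks a uniformly random remaining action.  One timing draw per performed
action is taken from its log-normal distribution; the sorted draws are
assigned to the constructed order, so timestamps are non-decreasing by
construction.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field

from .atls_reference import ReferenceModel
from .patient_engine import EngineConfig, run_session
from .scenario_model import TraumaScenario
from .session_scoring import EventLog, TraineeGroup


class ActionBehavior(BaseModel):
    """How one action is performed: marginal probability of performing it,
    and a log-normal timing distribution (median minutes, log-scale sigma)."""

    probability: float = Field(ge=0, le=1)
    time_median_min: float = Field(gt=0)
    time_sigma: float = Field(ge=0)


class BehaviorProfile(BaseModel):
    label: TraineeGroup
    adherence: float = Field(ge=0, le=1)
    actions: dict[str, ActionBehavior]
    #: actions sampled mutually exclusively (union prob = sum of marginals)
    exclusive_groups: list[list[str]] = Field(
        default_factory=lambda: [["thermal_blanket", "hot_liquids"]]
    )
    #: behavior for catalog actions not listed in ``actions``
    default_behavior: ActionBehavior = Field(
        default_factory=lambda: ActionBehavior(
            probability=1.0, time_median_min=60.0, time_sigma=0.5
        )
    )

    def behavior(self, action_id: str) -> ActionBehavior:
        return self.actions.get(action_id, self.default_behavior)


class CohortSpec(BaseModel):
    n_students: int = Field(default=28, ge=1)
    n_doctors: int = Field(default=13, ge=1)
    scenario_id: str = "pelvic_default"
    seed: int = 0
    student_profile: Optional[BehaviorProfile] = None
    doctor_profile: Optional[BehaviorProfile] = None


def default_profiles() -> tuple[BehaviorProfile, BehaviorProfile]:
    """Student and doctor profiles from the pilot cohort's per-action
    performance fractions, with assumed timing medians.

    Timing medians follow the reported response times where available
    (airway inspection from minute 3 for students vs the first two minutes
    for doctors; pelvic binder medians 72 vs 157 minutes) and plausible
    primary-survey pacing elsewhere; dispersions are assumptions, wider for
    students than doctors.
    """

    def beh(p: Fraction | float, median: float, sigma: float) -> ActionBehavior:
        return ActionBehavior(
            probability=float(p), time_median_min=median, time_sigma=sigma
        )

    student = BehaviorProfile(
        label=TraineeGroup.student,
        adherence=0.6,
        actions={
            "airway_inspection": beh(Fraction(20, 28), 4.0, 1.0),
            "airway_clearing": beh(0.3, 8.0, 1.0),
            "oxygenation": beh(Fraction(27, 28), 40.0, 1.2),
            "intubation": beh(Fraction(19, 28), 60.0, 1.0),
            "peripheral_iv": beh(0.9, 70.0, 0.8),
            "central_line": beh(0.9, 80.0, 0.8),
            "intraosseous_access": beh(0.9, 75.0, 0.8),
            "pelvic_binder": beh(Fraction(20, 28), 72.0, 1.1),
            "crystalloids": beh(Fraction(20, 28), 110.0, 0.8),
            "blood_transfusion": beh(Fraction(24, 28), 130.0, 0.8),
            "talk_to_patient": beh(0.0, 150.0, 0.6),
            "pupil_assessment": beh(0.0, 150.0, 0.6),
            "thermal_blanket": beh(Fraction(12, 28), 190.0, 0.5),
            "hot_liquids": beh(Fraction(6, 28), 190.0, 0.5),
        },
    )
    doctor = BehaviorProfile(
        label=TraineeGroup.doctor,
        adherence=0.8,
        actions={
            "airway_inspection": beh(Fraction(11, 13), 1.5, 0.6),
            "airway_clearing": beh(0.3, 5.0, 0.6),
            "oxygenation": beh(Fraction(13, 13), 20.0, 0.6),
            "intubation": beh(Fraction(7, 13), 45.0, 0.8),
            "peripheral_iv": beh(0.95, 90.0, 0.6),
            "central_line": beh(0.95, 100.0, 0.6),
            "intraosseous_access": beh(0.95, 95.0, 0.6),
            "pelvic_binder": beh(Fraction(10, 13), 157.0, 0.5),
            "crystalloids": beh(Fraction(11, 13), 140.0, 0.6),
            "blood_transfusion": beh(Fraction(12, 13), 160.0, 0.6),
            "talk_to_patient": beh(0.0, 150.0, 0.6),
            "pupil_assessment": beh(0.0, 150.0, 0.6),
            "thermal_blanket": beh(Fraction(2, 13), 180.0, 0.5),
            "hot_liquids": beh(Fraction(8, 13), 180.0, 0.5),
        },
    )
    return student, doctor


def sample_script(
    profile: BehaviorProfile,
    model: ReferenceModel,
    rng: np.random.Generator,
) -> list[tuple[str, int]]:
    """Sample one trainee's action script: (action_id, minute) pairs sorted
    by time.  Fully determined by the generator's state."""
    model.validate()
    exclusive_members = {
        a: tuple(group) for group in profile.exclusive_groups for a in group
    }

    # realize a reference sequence slot by slot, deciding performance once
    # per slot with the profile probability of the realized action
    performed: list[str] = []
    for slot in model.slots():
        kind = slot.kind.value
        if kind == "alternative":
            members = slot.actions
            if all(a in exclusive_members for a in members):
                probs = np.array(
                    [profile.behavior(a).probability for a in members]
                )
                p_union = min(1.0, float(probs.sum()))
                if p_union > 0 and rng.random() < p_union:
                    chosen = members[
                        int(rng.choice(len(members), p=probs / probs.sum()))
                    ]
                    performed.append(chosen)
            else:
                chosen = members[int(rng.integers(len(members)))]
                if rng.random() < profile.behavior(chosen).probability:
                    performed.append(chosen)
            continue
        action_id = slot.actions[0]
        if kind == "repeatable":
            reps = 1 + int(rng.integers(slot.extra_repetitions + 1))
        else:  # mandatory or optional: the profile owns the inclusion draw
            reps = 1
        if rng.random() < profile.behavior(action_id).probability:
            performed.extend([action_id] * reps)

    # step-wise order: follow reference order w.p. adherence, else jump
    remaining = list(performed)
    ordered: list[str] = []
    while remaining:
        if rng.random() < profile.adherence:
            pick = 0
        else:
            pick = int(rng.integers(len(remaining)))
        ordered.append(remaining.pop(pick))

    times = []
    for action_id in ordered:
        b = profile.behavior(action_id)
        t = rng.lognormal(mean=np.log(b.time_median_min), sigma=b.time_sigma)
        times.append(t)
    times.sort()
    return [
        (action_id, int(round(t)))
        for action_id, t in zip(ordered, times)
    ]


def generate_cohort(
    spec: CohortSpec,
    scenario: TraumaScenario,
    model: ReferenceModel,
    config: EngineConfig,
) -> list[EventLog]:
    """Simulate a full synthetic cohort through the patient engine.

    Each trainee gets an independent child RNG spawned from the spec seed,
    so the log set is reproducible and insensitive to cohort ordering.
    """
    if scenario.scenario_id != spec.scenario_id:
        raise ValueError(
            f"scenario {scenario.scenario_id!r} does not match spec "
            f"{spec.scenario_id!r}"
        )
    student_profile, doctor_profile = default_profiles()
    if spec.student_profile is not None:
        student_profile = spec.student_profile
    if spec.doctor_profile is not None:
        doctor_profile = spec.doctor_profile

    roster = (
        [(f"student_{i:03d}", student_profile) for i in range(spec.n_students)]
        + [(f"doctor_{i:03d}", doctor_profile) for i in range(spec.n_doctors)]
    )
    seeds = np.random.SeedSequence(spec.seed).spawn(len(roster))
    logs: list[EventLog] = []
    for (trainee_id, profile), seed in zip(roster, seeds):
        rng = np.random.default_rng(seed)
        script = sample_script(profile, model, rng)
        capped = [
            (a, min(t, config.horizon)) for a, t in script
        ]
        logs.append(run_session(
            scenario, capped, config,
            trainee_id=trainee_id, group=profile.label,
            log_id=f"{spec.scenario_id}:{trainee_id}",
        ))
    return logs
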