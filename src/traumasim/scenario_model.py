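"""Trauma scenarios and the action catalog.

A scenario describes the virtual patient a trainer configures: demographic
profile, vital signs on arrival, the remaining lifetime if the patient is
left untreated, the catalog of actions the trainee may take, and the lethal
bounds outside which the patient dies.  Scenarios are stored as YAML
(canonical) or JSON files with a schema version and a canonical key order so
that saving the same scenario twice yields byte-identical files.
"""

from __future__ import annotations

import json
from enum import Enum
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, ValidationError, field_validator, model_validator

SCHEMA_VERSION = 1

#: Body temperature at or below which the patient is considered hypothermic
#: and warming measures (thermal blanket, hot liquids) are indicated.
HYPOTHERMIA_THRESHOLD_C = 35.0

#: Names of the monitored vital signs, in canonical display order.
VITAL_NAMES = (
    "heart_rate",
    "systolic_bp",
    "diastolic_bp",
    "spo2",
    "respiratory_rate",
    "temperature",
    "consciousness",
)

#: Physiologic clipping ranges applied by the engine after every update.
PHYSIOLOGIC_RANGES = {
    "heart_rate": (0.0, 300.0),
    "systolic_bp": (0.0, 300.0),
    "diastolic_bp": (0.0, 200.0),
    "spo2": (0.0, 100.0),
    "respiratory_rate": (0.0, 80.0),
    "temperature": (20.0, 45.0),
    "consciousness": (3.0, 15.0),
}

BODY_REGIONS = ("head", "neck", "chest", "abdomen", "pelvis", "spine", "limbs")

PHASES = ("A", "B", "C", "D", "E")


class Sex(str, Enum):
    male = "male"
    female = "female"


class Phase(str, Enum):
    """ATLS primary-survey phases: Airway, Breathing, Circulation,
    Disability, Exposure."""

    A = "A"
    B = "B"
    C = "C"
    D = "D"
    E = "E"


class ScenarioFormatError(ValueError):
    """Raised when a scenario file cannot be parsed as the scenario schema."""


class ScenarioValidationError(ValueError):
    """Raised when a parsed scenario violates one or more invariants.

    Carries the full list of violations in ``errors``.
    """

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


class PatientProfile(BaseModel):
    sex: Sex
    age: int = Field(gt=0, le=120)
    injured_region: str = "pelvis"

    @field_validator("injured_region")
    @classmethod
    def _known_region(cls, v: str) -> str:
        if v not in BODY_REGIONS:
            raise ValueError(f"injured_region {v!r} not in {BODY_REGIONS}")
        return v


class VitalSignVector(BaseModel):
    """One reading of the seven-vital monitoring panel.

    Units: heart_rate bpm, blood pressures mmHg, spo2 percent,
    respiratory_rate breaths/min, temperature degrees Celsius, consciousness
    a GCS-like ordinal on 3-15.
    """

    heart_rate: float = Field(ge=0, le=300)
    systolic_bp: float = Field(ge=0, le=300)
    diastolic_bp: float = Field(ge=0, le=200)
    spo2: float = Field(ge=0, le=100)
    respiratory_rate: float = Field(ge=0, le=80)
    temperature: float = Field(ge=20, le=45)
    consciousness: float = Field(ge=3, le=15)

    @model_validator(mode="after")
    def _pulse_pressure_positive(self) -> "VitalSignVector":
        if not self.diastolic_bp < self.systolic_bp:
            raise ValueError(
                f"diastolic_bp ({self.diastolic_bp}) must be below "
                f"systolic_bp ({self.systolic_bp})"
            )
        return self

    @property
    def hypothermic(self) -> bool:
        """True when body temperature is at or below 35 degrees C."""
        return self.temperature <= HYPOTHERMIA_THRESHOLD_C

    def as_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in VITAL_NAMES}


class ActionEffect(BaseModel):
    """Effect of an action on one target quantity.

    ``target`` is a vital-sign name, ``"blood_volume"`` or
    ``"bleeding_rate"``.  ``delta`` is an additive change applied once,
    ``slope_factor`` a multiplier registered against the target's passive
    rate of change (deterioration slope, or the bleeding rate itself).
    A ``bleeding_rate`` effect with ``slope_factor=None`` defers to the
    engine's configured ``binder_bleeding_factor``.
    """

    target: str
    delta: float = 0.0
    slope_factor: Optional[float] = None

    @field_validator("target")
    @classmethod
    def _known_target(cls, v: str) -> str:
        if v not in VITAL_NAMES and v not in ("blood_volume", "bleeding_rate"):
            raise ValueError(f"unknown effect target {v!r}")
        return v


class ActionDefinition(BaseModel):
    action_id: str
    label: str
    phase: Phase
    effects: list[ActionEffect] = Field(default_factory=list)
    duration: int = Field(default=1, ge=0)  # simulated minutes occupied
    repeatable: int = Field(default=1, ge=1)  # max total repetitions
    prerequisites: list[str] = Field(default_factory=list)


class LethalBounds(BaseModel):
    """Per-vital closed intervals; the patient dies the first tick any
    vital lies strictly outside its interval."""

    bounds: dict[str, tuple[float, float]]

    @model_validator(mode="after")
    def _valid_bounds(self) -> "LethalBounds":
        for name, (lo, hi) in self.bounds.items():
            if name not in VITAL_NAMES:
                raise ValueError(f"unknown vital {name!r} in lethal bounds")
            if not lo < hi:
                raise ValueError(f"lethal bounds for {name} empty: ({lo}, {hi})")
        return self

    def contains(self, vitals: dict[str, float]) -> bool:
        return not self.violations(vitals)

    def violations(self, vitals: dict[str, float]) -> list[str]:
        out = []
        for name, (lo, hi) in self.bounds.items():
            v = vitals[name]
            if v < lo or v > hi:
                out.append(f"{name}={v} outside lethal bounds [{lo}, {hi}]")
        return out


class TraumaScenario(BaseModel):
    schema_version: int = SCHEMA_VERSION
    scenario_id: str
    profile: PatientProfile
    initial_vitals: VitalSignVector
    remaining_lifetime: int = Field(gt=0)  # minutes until death if untreated
    catalog_id: str = "default_pelvic"
    lethal_bounds: LethalBounds

    @model_validator(mode="after")
    def _initially_survivable(self) -> "TraumaScenario":
        violations = self.lethal_bounds.violations(self.initial_vitals.as_dict())
        if violations:
            raise ValueError(
                "initial vitals outside lethal bounds: " + "; ".join(violations)
            )
        return self


# --------------------------------------------------------------------------
# Default catalog
#
# The built-in catalog covers the pelvic-trauma primary survey: the nine
# actions scored in cohort reports (airway inspection, oxygenation,
# intubation, pelvic binder, blood transfusion, crystalloids, thermal
# blanket, hot liquids, talking to the patient) plus the auxiliary
# alternatives the default reference grammar needs (airway clearing, three
# vascular-access routes, pupil assessment).
# --------------------------------------------------------------------------

def default_action_catalog() -> list[ActionDefinition]:
    """Built-in action catalog for the pelvic-trauma scenario."""
    A, B, C, D, E = Phase.A, Phase.B, Phase.C, Phase.D, Phase.E
    eff = ActionEffect
    return [
        ActionDefinition(
            action_id="airway_inspection", label="Airway inspection", phase=A,
            duration=1,
        ),
        ActionDefinition(
            action_id="airway_clearing", label="Airway clearing", phase=A,
            duration=2,
        ),
        ActionDefinition(
            action_id="oxygenation", label="Patient oxygenation", phase=B,
            effects=[eff(target="spo2", delta=8.0, slope_factor=0.0)],
            duration=2,
        ),
        ActionDefinition(
            action_id="intubation", label="Patient intubation", phase=B,
            effects=[
                eff(target="spo2", delta=12.0, slope_factor=0.0),
                eff(target="respiratory_rate", slope_factor=0.0),
            ],
            duration=5,
        ),
        ActionDefinition(
            action_id="peripheral_iv", label="Peripheral IV access", phase=C,
            duration=2,
        ),
        ActionDefinition(
            action_id="central_line", label="Central venous access", phase=C,
            duration=5,
        ),
        ActionDefinition(
            action_id="intraosseous_access", label="Intraosseous access", phase=C,
            duration=2,
        ),
        ActionDefinition(
            action_id="pelvic_binder", label="Pelvic binder placement", phase=C,
            effects=[eff(target="bleeding_rate")],  # factor from engine config
            duration=3,
        ),
        ActionDefinition(
            action_id="crystalloids", label="Crystalloids administration", phase=C,
            effects=[eff(target="blood_volume", delta=0.10)],
            duration=3, repeatable=3,
        ),
        ActionDefinition(
            action_id="blood_transfusion", label="Blood transfusion", phase=C,
            effects=[eff(target="blood_volume", delta=0.15)],
            duration=5, repeatable=3,
        ),
        ActionDefinition(
            action_id="talk_to_patient", label="Talk to the patient", phase=D,
            duration=2,
        ),
        ActionDefinition(
            action_id="pupil_assessment", label="Pupil response assessment",
            phase=D, duration=1,
        ),
        ActionDefinition(
            action_id="thermal_blanket", label="Thermal blanket", phase=E,
            effects=[eff(target="temperature", delta=0.5, slope_factor=0.0)],
            duration=2,
        ),
        ActionDefinition(
            action_id="hot_liquids", label="Hot liquids administration", phase=E,
            effects=[eff(target="temperature", delta=1.0, slope_factor=0.0)],
            duration=2,
        ),
    ]


_CATALOG_REGISTRY: dict[str, list[ActionDefinition]] = {}


def get_catalog(catalog_id: str) -> list[ActionDefinition]:
    """Resolve a catalog id to its action list."""
    if catalog_id == "default_pelvic":
        return default_action_catalog()
    try:
        return _CATALOG_REGISTRY[catalog_id]
    except KeyError:
        raise KeyError(f"unknown catalog_id {catalog_id!r}") from None


def register_catalog(catalog_id: str, actions: list[ActionDefinition]) -> None:
    ids = [a.action_id for a in actions]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate action_ids in catalog")
    _CATALOG_REGISTRY[catalog_id] = list(actions)


def default_lethal_bounds() -> LethalBounds:
    return LethalBounds(bounds={
        "heart_rate": (20.0, 220.0),
        "systolic_bp": (60.0, 250.0),
        "diastolic_bp": (20.0, 150.0),
        "spo2": (65.0, 100.0),
        "respiratory_rate": (5.0, 60.0),
        "temperature": (30.0, 42.0),
        "consciousness": (3.0, 15.0),
    })


def default_scenario() -> TraumaScenario:
    """The built-in pelvic-trauma case: a hemodynamically compromised adult
    with borderline temperature (hypothermia develops untreated) and a
    240-minute remaining lifetime."""
    return TraumaScenario(
        scenario_id="pelvic_default",
        profile=PatientProfile(sex=Sex.male, age=32, injured_region="pelvis"),
        initial_vitals=VitalSignVector(
            heart_rate=110.0,
            systolic_bp=95.0,
            diastolic_bp=60.0,
            spo2=94.0,
            respiratory_rate=22.0,
            temperature=35.5,
            consciousness=13.0,
        ),
        remaining_lifetime=240,
        catalog_id="default_pelvic",
        lethal_bounds=default_lethal_bounds(),
    )


# --------------------------------------------------------------------------
# Serialization
# --------------------------------------------------------------------------

_CANONICAL_KEY_ORDER = (
    "schema_version", "scenario_id", "profile", "initial_vitals",
    "remaining_lifetime", "catalog_id", "lethal_bounds",
)


def _scenario_to_plain(scenario: TraumaScenario) -> dict:
    data = scenario.model_dump(mode="json")
    # tuples -> lists for YAML friendliness, canonical top-level order
    data["lethal_bounds"] = {
        "bounds": {
            k: list(v)
            for k, v in sorted(data["lethal_bounds"]["bounds"].items())
        }
    }
    return {key: data[key] for key in _CANONICAL_KEY_ORDER}


def save_scenario(scenario: TraumaScenario, path: str | Path) -> None:
    """Write a scenario to YAML (or JSON if the path ends in .json).

    Output is canonical: fixed top-level key order, sorted nested keys, so
    two saves of the same scenario are byte-identical.  Re-validates before
    writing and refuses to serialize an invalid scenario.
    """
    try:  # a mutated-in-place model may no longer satisfy the invariants
        TraumaScenario.model_validate(scenario.model_dump())
    except ValidationError as exc:
        raise ScenarioValidationError(
            [str(e["msg"]) for e in exc.errors()]
        ) from exc
    data = _scenario_to_plain(scenario)
    path = Path(path)
    if path.suffix.lower() == ".json":
        text = json.dumps(data, indent=2, sort_keys=False) + "\n"
    else:
        text = yaml.safe_dump(data, sort_keys=False)
    path.write_text(text)


def load_scenario(path: str | Path) -> TraumaScenario:
    """Load and fully validate a scenario from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            raw = json.loads(text)
        else:
            raw = yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ScenarioFormatError(f"cannot parse {path.name}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ScenarioFormatError(f"{path.name}: scenario file must be a mapping")
    try:
        return TraumaScenario.model_validate(raw)
    except ValidationError as exc:
        msgs = [
            f"{'.'.join(str(loc) for loc in e['loc'])}: {e['msg']}"
            for e in exc.errors()
        ]
        raise ScenarioValidationError(msgs) from exc
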