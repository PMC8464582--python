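"""ATLS primary-survey reference grammar.

The set of treatment sequences consistent with ATLS guidance for the pelvic
scenario is encoded as a small phase-structured grammar: the phases
A (airway) through E (exposure) in strict order, each phase an ordered list
of slots.  A slot is one of

* ``mandatory(a)``       — action ``a`` appears exactly once;
* ``alternative(a1..am)``— exactly one of ``m`` interchangeable actions;
* ``optional(a)``        — action ``a`` appears 0 or 1 times;
* ``repeatable(a, r)``   — action ``a`` appears 1 to ``1+r`` consecutive
  times (``r`` extra repetitions beyond the first).

Enumerating the default grammar yields 432 distinct sequences whose length
distribution over 8..14 actions is 12, 48, 96, 120, 96, 48, 12 — the
coefficients of 12*(1+x)^2*(1+x+x^2)^2, arising from two optional slots,
two repeatable slots with up to two extra repetitions, and alternative
slots of sizes 3, 2 and 2.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Sequence

from .scenario_model import ActionDefinition, default_action_catalog


class SlotKind(str, Enum):
    mandatory = "mandatory"
    alternative = "alternative"
    optional = "optional"
    repeatable = "repeatable"


@dataclass(frozen=True)
class Slot:
    kind: SlotKind
    actions: tuple[str, ...]          # one entry unless alternative
    extra_repetitions: int = 0        # repeatable only

    def __post_init__(self):
        if not self.actions:
            raise ValueError("slot needs at least one action")
        if self.kind is not SlotKind.alternative and len(self.actions) != 1:
            raise ValueError(f"{self.kind.value} slot takes exactly one action")
        if self.kind is SlotKind.repeatable and self.extra_repetitions < 0:
            raise ValueError("extra_repetitions must be >= 0")

    def expansions(self) -> Iterator[tuple[str, ...]]:
        """Every token run this slot can contribute to a sequence."""
        if self.kind is SlotKind.mandatory:
            yield (self.actions[0],)
        elif self.kind is SlotKind.alternative:
            for a in self.actions:
                yield (a,)
        elif self.kind is SlotKind.optional:
            yield ()
            yield (self.actions[0],)
        else:  # repeatable: 1..1+r consecutive occurrences
            for reps in range(1, self.extra_repetitions + 2):
                yield (self.actions[0],) * reps


def mandatory(action: str) -> Slot:
    return Slot(SlotKind.mandatory, (action,))


def alternative(*actions: str) -> Slot:
    return Slot(SlotKind.alternative, tuple(actions))


def optional(action: str) -> Slot:
    return Slot(SlotKind.optional, (action,))


def repeatable(action: str, extra_repetitions: int) -> Slot:
    return Slot(SlotKind.repeatable, (action,), extra_repetitions)


@dataclass(frozen=True)
class ReferenceModel:
    """Phase-ordered slot grammar over an action catalog."""

    phases: tuple[tuple[str, tuple[Slot, ...]], ...]
    catalog: tuple[ActionDefinition, ...] = field(
        default_factory=lambda: tuple(default_action_catalog())
    )

    def slots(self) -> tuple[Slot, ...]:
        return tuple(s for _, phase_slots in self.phases for s in phase_slots)

    def validate(self) -> None:
        known = {a.action_id for a in self.catalog}
        for _, phase_slots in self.phases:
            for slot in phase_slots:
                unknown = set(slot.actions) - known
                if unknown:
                    raise ValueError(
                        f"grammar references unknown actions: {sorted(unknown)}"
                    )


def default_reference_model() -> ReferenceModel:
    """The pelvic-scenario grammar.

    Backbone of eight slots across A-E; airway clearing and intubation are
    optional; crystalloids and blood transfusion may each be repeated up to
    two extra times; vascular access (3 routes), disability assessment
    (2 modes) and warming (2 measures) are alternatives.
    """
    return ReferenceModel(phases=(
        ("A", (
            mandatory("airway_inspection"),
            optional("airway_clearing"),
        )),
        ("B", (
            mandatory("oxygenation"),
            optional("intubation"),
        )),
        ("C", (
            alternative("peripheral_iv", "central_line", "intraosseous_access"),
            mandatory("pelvic_binder"),
            repeatable("crystalloids", extra_repetitions=2),
            repeatable("blood_transfusion", extra_repetitions=2),
        )),
        ("D", (
            alternative("talk_to_patient", "pupil_assessment"),
        )),
        ("E", (
            alternative("thermal_blanket", "hot_liquids"),
        )),
    ))


def enumerate_sequences(model: ReferenceModel) -> list[tuple[str, ...]]:
    """All distinct action sequences the grammar generates, sorted
    lexicographically.  Deterministic and duplicate-free.

    The result is memoized on the (frozen) model instance, since scoring
    and cohort sampling enumerate the same model many times.
    """
    cached = getattr(model, "_enum_cache", None)
    if cached is None:
        model.validate()
        cached = sorted({
            tuple(itertools.chain.from_iterable(choice))
            for choice in itertools.product(
                *(slot.expansions() for slot in model.slots())
            )
        })
        object.__setattr__(model, "_enum_cache", cached)
    return list(cached)


def length_histogram(model: ReferenceModel) -> dict[int, int]:
    """Histogram mapping sequence length to the number of reference
    sequences of that length."""
    counts = Counter(len(s) for s in enumerate_sequences(model))
    return dict(sorted(counts.items()))


def is_reference(sequence: Sequence[str], model: ReferenceModel) -> bool:
    """Whether ``sequence`` is generated by the grammar.

    Matches slot by slot with backtracking rather than looking the sequence
    up in the enumerated set; unknown action ids simply fail to match.
    """
    model.validate()
    slots = model.slots()
    seq = tuple(sequence)

    def match(slot_idx: int, pos: int) -> bool:
        if slot_idx == len(slots):
            return pos == len(seq)
        for run in slots[slot_idx].expansions():
            n = len(run)
            if seq[pos:pos + n] == run and match(slot_idx + 1, pos + n):
                return True
        return False

    return match(0, 0)
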