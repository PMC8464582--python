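import pytest

from traumasim import (
    ActionDefinition,
    EngineConfig,
    Phase,
    ReferenceModel,
    default_reference_model,
    default_scenario,
)


@pytest.fixture(scope="session")
def model():
    """Default reference model, shared so the enumeration cache is reused."""
    return default_reference_model()


@pytest.fixture()
def scenario():
    return default_scenario()


@pytest.fixture()
def config():
    return EngineConfig()


def make_catalog(*action_ids: str) -> tuple[ActionDefinition, ...]:
    """Minimal catalog for toy grammars (all actions in phase A)."""
    return tuple(
        ActionDefinition(action_id=a, label=a, phase=Phase.A)
        for a in action_ids
    )


def make_model(slots, *action_ids: str) -> ReferenceModel:
    """Toy single-phase reference model over a synthetic catalog."""
    return ReferenceModel(
        phases=(("A", tuple(slots)),), catalog=make_catalog(*action_ids)
    )
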