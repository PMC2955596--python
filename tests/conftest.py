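import pytest

from mobscore import (
    Archetype,
    ParticipantAttrs,
    default_registry,
)


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture
def walker_attrs():
    return ParticipantAttrs(
        participant_id="p1", age=70, sex="M", archetype=Archetype.PROSTHESIS_WALKER
    )


@pytest.fixture
def wheelchair_attrs():
    return ParticipantAttrs(
        participant_id="p1", age=70, sex="M", archetype=Archetype.WHEELCHAIR_USER
    )
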