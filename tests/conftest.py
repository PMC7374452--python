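from datetime import datetime, timezone

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")

from qsrec.planner import Action, BinaryClause, Effect, WorldState
from qsrec.triggers import TriggerGoal


@pytest.fixture
def tue_afternoon() -> datetime:
    # Tuesday 2026-01-06 17:30 UTC
    return datetime(2026, 1, 6, 17, 30, tzinfo=timezone.utc)


@pytest.fixture
def warmup_catalog() -> list[Action]:
    """Two-step catalog: warming up enables the activity that meets the goal."""
    a = Action(
        "a_warmup",
        "physical_activity",
        preconditions=(),
        goals=(Effect("warmed_up", "set", True),),
    )
    b = Action(
        "b_activity",
        "physical_activity",
        preconditions=(BinaryClause("warmed_up", "eq", True),),
        goals=(Effect("activity_done", "set", True),),
    )
    return [a, b]


@pytest.fixture
def activity_goal() -> TriggerGoal:
    return TriggerGoal(targets=(("activity_done", "increase"),))


@pytest.fixture
def empty_state() -> WorldState:
    return WorldState({"warmed_up": False})
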