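"""Action filter and plan construction.

Actions in the catalog carry *binary-clause* preconditions (single
comparator conditions over one state variable) and *goal effects* (the
consequences the action is expected to have on the user).  Filtering
keeps only actions whose preconditions all hold in the current world
state — assembled from the QS model's derived indicators plus contextual
information — and whose effects address at least one trigger-goal
target.

Actions can also be concatenated into *plans*: ordered sequences in
which each step's preconditions are guaranteed by the initial state plus
the effects of its predecessors, and whose combined effects cover the
trigger goal.  The world is closed: a clause over an absent variable is
false, so nothing is ever recommended on unknown state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

from .errors import DomainError, EvaluationError, SchemaError
from .triggers import TriggerGoal

__all__ = [
    "BinaryClause",
    "Effect",
    "Action",
    "WorldState",
    "Plan",
    "clause_satisfied",
    "preconditions_met",
    "apply_effects",
    "filter_actions",
    "build_plans",
    "plan_is_valid",
    "validate_catalog",
    "load_catalog",
    "ACTION_CATEGORIES",
    "DIRECTION_COMPAT",
]

ACTION_CATEGORIES = (
    "physical_activity",
    "active_game",
    "nutrition_education",
    "motivation",
    "reminder",
)

_CLAUSE_COMPARATORS = ("eq", "ne", "lt", "le", "gt", "ge", "in_set")
_EFFECT_OPS = ("set", "increase", "decrease")

# Which effect operations count as addressing a goal direction.
DIRECTION_COMPAT = {
    "increase": {"set", "increase"},
    "decrease": {"set", "decrease"},
    "maintain": {"set"},
}


@dataclass(frozen=True)
class BinaryClause:
    variable: str
    comparator: str
    value: Any

    def __post_init__(self) -> None:
        if self.comparator not in _CLAUSE_COMPARATORS:
            raise SchemaError(f"unknown comparator {self.comparator!r}")
        if self.comparator == "in_set" and not isinstance(self.value, (set, frozenset, list, tuple)):
            raise SchemaError("in_set clause requires a collection value")
        if self.comparator == "in_set":
            object.__setattr__(self, "value", frozenset(self.value))


@dataclass(frozen=True)
class Effect:
    variable: str
    operation: str
    value: Any

    def __post_init__(self) -> None:
        if self.operation not in _EFFECT_OPS:
            raise SchemaError(f"unknown effect operation {self.operation!r}")
        if self.operation in ("increase", "decrease") and not isinstance(
            self.value, (int, float)
        ):
            raise SchemaError(f"{self.operation} effect requires a numeric value")


@dataclass(frozen=True)
class Action:
    action_id: str
    category: str
    preconditions: tuple[BinaryClause, ...] = ()
    goals: tuple[Effect, ...] = ()
    content: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "preconditions", tuple(self.preconditions))
        object.__setattr__(self, "goals", tuple(self.goals))
        if not self.goals:
            raise SchemaError(f"action {self.action_id!r} has no goals")
        if self.category not in ACTION_CATEGORIES:
            raise SchemaError(
                f"action {self.action_id!r}: unknown category {self.category!r}"
            )


@dataclass(frozen=True)
class WorldState:
    """Immutable variable assignment; contextual plus QS-derived variables."""

    assignment: Mapping[str, Any] = field(default_factory=dict)

    def get(self, variable: str, default: Any = None) -> Any:
        return self.assignment.get(variable, default)

    def __contains__(self, variable: str) -> bool:
        return variable in self.assignment

    def __getitem__(self, variable: str) -> Any:
        return self.assignment[variable]

    def with_updates(self, updates: Mapping[str, Any]) -> "WorldState":
        merged = dict(self.assignment)
        merged.update(updates)
        return WorldState(merged)


def clause_satisfied(clause: BinaryClause, state: WorldState | Mapping[str, Any]) -> bool:
    """Evaluate one binary clause; absent variables are false (closed world)."""
    assignment = state.assignment if isinstance(state, WorldState) else state
    if clause.variable not in assignment:
        return False
    current = assignment[clause.variable]
    try:
        if clause.comparator == "eq":
            return current == clause.value
        if clause.comparator == "ne":
            return current != clause.value
        if clause.comparator == "in_set":
            return current in clause.value
        if clause.comparator == "lt":
            return current < clause.value
        if clause.comparator == "le":
            return current <= clause.value
        if clause.comparator == "gt":
            return current > clause.value
        return current >= clause.value
    except TypeError:
        raise EvaluationError(
            f"cannot compare {clause.variable!r}={current!r} with {clause.value!r}"
        ) from None


def preconditions_met(action: Action, state: WorldState) -> bool:
    return all(clause_satisfied(c, state) for c in action.preconditions)


def apply_effects(state: WorldState, action: Action) -> WorldState:
    """Apply an action's effects in listed order; the input state is unchanged.

    ``increase``/``decrease`` on an absent variable start from 0.
    """
    assignment = dict(state.assignment)
    for eff in action.goals:
        if eff.operation == "set":
            assignment[eff.variable] = eff.value
        else:
            current = assignment.get(eff.variable, 0)
            if not isinstance(current, (int, float)) or isinstance(current, bool):
                raise EvaluationError(
                    f"{eff.operation} on non-numeric variable {eff.variable!r}={current!r}"
                )
            delta = eff.value if eff.operation == "increase" else -eff.value
            assignment[eff.variable] = current + delta
    return WorldState(assignment)


def _addresses(action: Action, target: tuple[str, str]) -> bool:
    variable, direction = target
    compat = DIRECTION_COMPAT[direction]
    return any(e.variable == variable and e.operation in compat for e in action.goals)


def filter_actions(
    catalog: Sequence[Action], state: WorldState, goal: TriggerGoal
) -> list[Action]:
    """Actions whose preconditions hold and that address >= 1 goal target."""
    return sorted(
        (
            a
            for a in catalog
            if preconditions_met(a, state) and any(_addresses(a, t) for t in goal.targets)
        ),
        key=lambda a: a.action_id,
    )


@dataclass(frozen=True)
class Plan:
    steps: tuple[Action, ...]

    def action_ids(self) -> tuple[str, ...]:
        return tuple(a.action_id for a in self.steps)


def plan_is_valid(plan: Plan, state: WorldState) -> bool:
    """Step-by-step replay check of the stepwise-precondition invariant."""
    current = state
    for action in plan.steps:
        if not preconditions_met(action, current):
            return False
        current = apply_effects(current, action)
    return True


def _covers_goal(plan_actions: Sequence[Action], goal: TriggerGoal, require_all: bool) -> bool:
    addressed = [
        any(_addresses(a, t) for a in plan_actions) for t in goal.targets
    ]
    return all(addressed) if require_all else any(addressed)


def build_plans(
    catalog: Sequence[Action],
    state: WorldState,
    goal: TriggerGoal,
    max_len: int = 3,
    require_all_targets: bool = True,
) -> list[Plan]:
    """All valid plans of length <= ``max_len`` covering the trigger goal.

    Depth-bounded search over sequences of distinct actions: each step's
    preconditions must hold in the state produced by its predecessors,
    and the combined effects must address every goal target (or at least
    one, with ``require_all_targets=False``).  Plans are returned in
    deterministic lexicographic order by (length, action ids).  The
    search is exhaustive — exact at catalog scale, where sequences over
    a handful of actions are few.
    """
    if max_len < 1:
        raise DomainError(f"max_len must be >= 1, got {max_len}")
    ordered = sorted(catalog, key=lambda a: a.action_id)
    found: list[Plan] = []

    def extend(prefix: list[Action], current: WorldState) -> None:
        if prefix and _covers_goal(prefix, goal, require_all_targets):
            found.append(Plan(steps=tuple(prefix)))
        if len(prefix) == max_len:
            return
        used = {a.action_id for a in prefix}
        for action in ordered:
            if action.action_id in used or not preconditions_met(action, current):
                continue
            extend(prefix + [action], apply_effects(current, action))

    extend([], state)
    found.sort(key=lambda p: (len(p.steps), p.action_ids()))
    return found


# ---------------------------------------------------------------------------
# Catalog documents

_VARIABLE_TYPES = {"number", "string", "boolean"}
_PY_TYPES = {"number": (int, float), "string": (str,), "boolean": (bool,)}


def validate_catalog(doc: Mapping[str, Any]) -> tuple[list[Action], list[str]]:
    """Validate a catalog document against its own variable dictionary.

    Returns (actions, errors); ``actions`` holds every entry that
    validated individually, ``errors`` one message per violation with
    the offending action_id and field path.
    """
    errors: list[str] = []
    variables: Mapping[str, str] = doc.get("variables", {})
    for name, vtype in variables.items():
        if vtype not in _VARIABLE_TYPES:
            errors.append(f"variables.{name}: unknown type {vtype!r}")
    actions: list[Action] = []
    seen: dict[str, int] = {}
    for i, entry in enumerate(doc.get("actions", [])):
        aid = entry.get("action_id", f"<entry {i}>")
        if aid in seen:
            errors.append(f"actions[{i}].action_id: duplicate of actions[{seen[aid]}] ({aid!r})")
            continue
        seen[aid] = i
        entry_errors = []
        for j, clause in enumerate(entry.get("preconditions", [])):
            path = f"actions[{i}].preconditions[{j}]"
            entry_errors += _check_typed(clause, "variable", variables, path, aid)
        for j, eff in enumerate(entry.get("goals", [])):
            path = f"actions[{i}].goals[{j}]"
            entry_errors += _check_typed(eff, "variable", variables, path, aid)
        if not entry.get("goals"):
            entry_errors.append(f"actions[{i}].goals: empty ({aid!r})")
        if entry_errors:
            errors += entry_errors
            continue
        try:
            actions.append(
                Action(
                    action_id=aid,
                    category=entry.get("category", ""),
                    preconditions=tuple(
                        BinaryClause(c["variable"], c["comparator"], c["value"])
                        for c in entry.get("preconditions", [])
                    ),
                    goals=tuple(
                        Effect(e["variable"], e["operation"], e["value"])
                        for e in entry.get("goals", [])
                    ),
                    content=entry.get("content", {}),
                )
            )
        except (SchemaError, KeyError) as exc:
            errors.append(f"actions[{i}] ({aid!r}): {exc}")
    return actions, errors


def _check_typed(
    clause: Mapping[str, Any],
    key: str,
    variables: Mapping[str, str],
    path: str,
    action_id: str,
) -> list[str]:
    errs = []
    var = clause.get(key)
    if var is None:
        errs.append(f"{path}.{key}: missing ({action_id!r})")
        return errs
    if variables and var not in variables:
        errs.append(f"{path}.{key}: undeclared variable {var!r} ({action_id!r})")
        return errs
    vtype = variables.get(var)
    value = clause.get("value")
    comparator = clause.get("comparator")
    if vtype and value is not None and comparator != "in_set":
        ok = isinstance(value, _PY_TYPES[vtype]) and not (
            vtype == "number" and isinstance(value, bool)
        )
        if not ok:
            errs.append(
                f"{path}.value: {value!r} incompatible with {vtype} variable {var!r}"
                f" ({action_id!r})"
            )
    return errs


def load_catalog(source) -> list[Action]:
    """Load a JSON catalog, raising :class:`SchemaError` on any violation."""
    if hasattr(source, "read"):
        doc = json.load(source)
    else:
        with open(source) as fh:
            doc = json.load(fh)
    actions, errors = validate_catalog(doc)
    if errors:
        raise SchemaError("invalid catalog:\n" + "\n".join(errors))
    return actions
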