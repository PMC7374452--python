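"""Recommendation trigger engine.

A recommendation can fire for three reasons: the weekly schedule reaches
a configured slot, the child arrives near a place of a configured
category (geofencing), or an ingested record changes a derived indicator
of the QS model past a threshold.  Every firing carries a *trigger
goal* — the set of user-model variables (with desired directions) that
caused it — which the downstream action filter must address.

Model-update rules are edge-triggered on the ingestion change set:
holding above a threshold without a new change produces no further
events, which avoids recommendation storms.  Each rule additionally has
a refractory period (default 60 minutes) during which it will not
re-fire.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import datetime, time, timedelta
from typing import Any, Mapping, Sequence

from .errors import ConfigurationError, DomainError, SchemaError

__all__ = [
    "TriggerRule",
    "TriggerGoal",
    "TriggerEvent",
    "TriggerEngine",
    "haversine_distance",
    "compose_trigger_goal",
    "evaluate_schedule_triggers",
    "evaluate_location_triggers",
    "evaluate_model_triggers",
    "evaluate_triggers",
    "load_trigger_rules",
]

EARTH_RADIUS_M = 6_371_000.0

_KINDS = ("schedule", "location", "model_update")
_DIRECTIONS = ("increase", "decrease", "maintain")
_DAY_NAMES = ("monday", "tuesday", "wednesday", "thursday", "friday", "saturday", "sunday")
_COMPARATORS = {
    "lt": lambda a, b: a < b,
    "le": lambda a, b: a <= b,
    "gt": lambda a, b: a > b,
    "ge": lambda a, b: a >= b,
    "eq": lambda a, b: a == b,
    "ne": lambda a, b: a != b,
}


def haversine_distance(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Great-circle distance in meters between two (lat, lon) points."""
    for lat, lon in (a, b):
        if not -90 <= lat <= 90 or not -180 <= lon <= 180:
            raise DomainError(f"coordinate ({lat}, {lon}) out of range")
    lat1, lon1, lat2, lon2 = map(math.radians, (*a, *b))
    s = (
        math.sin((lat2 - lat1) / 2) ** 2
        + math.cos(lat1) * math.cos(lat2) * math.sin((lon2 - lon1) / 2) ** 2
    )
    return 2 * EARTH_RADIUS_M * math.asin(math.sqrt(s))


@dataclass(frozen=True)
class TriggerGoal:
    """Variables (with desired directions) a recommendation must address."""

    targets: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        names = [v for v, _ in self.targets]
        if len(names) != len(set(names)):
            raise SchemaError("goal variables must be unique")

    def variables(self) -> tuple[str, ...]:
        return tuple(v for v, _ in self.targets)


@dataclass(frozen=True)
class TriggerRule:
    rule_id: str
    kind: str
    predicate: Mapping[str, Any]
    goal_variables: tuple[tuple[str, str], ...]
    refractory_minutes: float = 60.0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ConfigurationError(f"rule {self.rule_id!r}: unknown kind {self.kind!r}")
        object.__setattr__(self, "goal_variables", tuple(map(tuple, self.goal_variables)))
        for _, direction in self.goal_variables:
            if direction not in _DIRECTIONS:
                raise ConfigurationError(
                    f"rule {self.rule_id!r}: unknown direction {direction!r}"
                )
        if self.kind == "location":
            radius = self.predicate.get("radius_m", 200.0)
            if not radius > 0:
                raise ConfigurationError(f"rule {self.rule_id!r}: radius must be positive")
        if self.kind == "model_update":
            threshold = self.predicate.get("threshold")
            if isinstance(threshold, (int, float)) and not math.isfinite(threshold):
                raise ConfigurationError(f"rule {self.rule_id!r}: threshold must be finite")


@dataclass(frozen=True)
class TriggerEvent:
    timestamp: datetime
    rule_id: str
    kind: str
    goal: TriggerGoal
    detail: Mapping[str, Any] = field(default_factory=dict)


def compose_trigger_goal(rule: TriggerRule) -> TriggerGoal:
    """Goal of a rule: its goal variables, first-listed direction on duplicates."""
    if not rule.goal_variables:
        raise ConfigurationError(f"rule {rule.rule_id!r} has no goal variables")
    seen: dict[str, str] = {}
    for var, direction in rule.goal_variables:
        seen.setdefault(var, direction)
    return TriggerGoal(targets=tuple(seen.items()))


def _in_refractory(rule: TriggerRule, now: datetime, last_fired: Mapping[str, datetime]) -> bool:
    last = last_fired.get(rule.rule_id)
    return last is not None and now - last < timedelta(minutes=rule.refractory_minutes)


def _parse_hhmm(text: str) -> time:
    try:
        h, m = text.split(":")
        return time(int(h), int(m))
    except (ValueError, AttributeError):
        raise ConfigurationError(f"malformed time {text!r}, expected HH:MM") from None


def _slot_contains(slot: Mapping[str, Any], now: datetime) -> bool:
    days = slot.get("days", [slot["day"]] if "day" in slot else None)
    if days is None or "start" not in slot or "end" not in slot:
        raise ConfigurationError(f"malformed schedule slot {slot!r}")
    day_idx = {d if isinstance(d, int) else _DAY_NAMES.index(str(d).lower()) for d in days}
    start, end = _parse_hhmm(slot["start"]), _parse_hhmm(slot["end"])
    # half-open [start, end)
    return now.weekday() in day_idx and start <= now.time() < end


def evaluate_schedule_triggers(
    rules: Sequence[TriggerRule],
    now: datetime,
    schedule: Mapping[str, Sequence[Mapping[str, Any]]] | None = None,
    last_fired: Mapping[str, datetime] | None = None,
) -> list[TriggerEvent]:
    """Fire schedule rules whose weekly slot contains ``now``.

    A rule's predicate is either an explicit slot ({days, start, end}) or
    a named slot ({"slot": name}) resolved against the child's schedule.
    """
    last_fired = last_fired or {}
    events = []
    for rule in sorted(rules, key=lambda r: r.rule_id):
        if rule.kind != "schedule":
            continue
        if "slot" in rule.predicate:
            if schedule is None or rule.predicate["slot"] not in schedule:
                raise ConfigurationError(
                    f"rule {rule.rule_id!r}: schedule slot {rule.predicate['slot']!r} unknown"
                )
            slots = schedule[rule.predicate["slot"]]
        else:
            slots = [rule.predicate]
        if any(_slot_contains(s, now) for s in slots) and not _in_refractory(
            rule, now, last_fired
        ):
            events.append(
                TriggerEvent(now, rule.rule_id, "schedule", compose_trigger_goal(rule))
            )
    return events


def evaluate_location_triggers(
    rules: Sequence[TriggerRule],
    position: tuple[float, float],
    places: Sequence[tuple[str, str, float, float]],
    now: datetime | None = None,
    last_fired: Mapping[str, datetime] | None = None,
) -> list[TriggerEvent]:
    """Fire location rules with a place of the right category inside the geofence.

    ``places`` rows are (place_id, category, latitude, longitude).  The
    nearest qualifying place is recorded in the event detail.
    """
    last_fired = last_fired or {}
    now = now or datetime.now().astimezone()
    events = []
    for rule in sorted(rules, key=lambda r: r.rule_id):
        if rule.kind != "location":
            continue
        category = rule.predicate["category"]
        radius = float(rule.predicate.get("radius_m", 200.0))
        hits = [
            (haversine_distance(position, (lat, lon)), place_id)
            for place_id, cat, lat, lon in places
            if cat == category
        ]
        hits = [(d, pid) for d, pid in hits if d <= radius]
        if hits and not _in_refractory(rule, now, last_fired):
            dist, place_id = min(hits)
            events.append(
                TriggerEvent(
                    now,
                    rule.rule_id,
                    "location",
                    compose_trigger_goal(rule),
                    detail={"place_id": place_id, "distance_m": dist},
                )
            )
    return events


def evaluate_model_triggers(
    rules: Sequence[TriggerRule],
    changed: set[str],
    indicators: Mapping[str, Any],
    now: datetime | None = None,
    last_fired: Mapping[str, datetime] | None = None,
) -> list[TriggerEvent]:
    """Fire model-update rules whose variable just changed and crosses its threshold.

    Edge-triggered: a rule only fires when its variable is in the
    ingestion change set, never merely because its condition holds.
    """
    last_fired = last_fired or {}
    now = now or datetime.now().astimezone()
    events = []
    for rule in sorted(rules, key=lambda r: r.rule_id):
        if rule.kind != "model_update":
            continue
        var = rule.predicate["variable"]
        if var not in indicators:
            raise ConfigurationError(
                f"rule {rule.rule_id!r} references unknown variable {var!r}"
            )
        if var not in changed:
            continue
        cmp = _COMPARATORS.get(rule.predicate["comparator"])
        if cmp is None:
            raise ConfigurationError(
                f"rule {rule.rule_id!r}: unknown comparator {rule.predicate['comparator']!r}"
            )
        if cmp(indicators[var], rule.predicate["threshold"]) and not _in_refractory(
            rule, now, last_fired
        ):
            events.append(
                TriggerEvent(
                    now,
                    rule.rule_id,
                    "model_update",
                    compose_trigger_goal(rule),
                    detail={"variable": var, "value": indicators[var]},
                )
            )
    return events


def evaluate_triggers(
    rules: Sequence[TriggerRule],
    now: datetime,
    schedule: Mapping[str, Any] | None = None,
    position: tuple[float, float] | None = None,
    places: Sequence[tuple[str, str, float, float]] = (),
    changed: set[str] | None = None,
    indicators: Mapping[str, Any] | None = None,
    last_fired: Mapping[str, datetime] | None = None,
) -> list[TriggerEvent]:
    """Evaluate all rule kinds; events ordered schedule, location, model_update."""
    events = evaluate_schedule_triggers(rules, now, schedule, last_fired)
    if position is not None:
        events += evaluate_location_triggers(rules, position, places, now, last_fired)
    if changed is not None and indicators is not None:
        events += evaluate_model_triggers(rules, changed, indicators, now, last_fired)
    return events


class TriggerEngine:
    """Stateful wrapper tracking per-rule last-fired times (refractory)."""

    def __init__(self, rules: Sequence[TriggerRule]):
        self.rules = tuple(rules)
        self.last_fired: dict[str, datetime] = {}

    def poll(self, now: datetime, **kwargs: Any) -> list[TriggerEvent]:
        events = evaluate_triggers(self.rules, now, last_fired=self.last_fired, **kwargs)
        for ev in events:
            self.last_fired[ev.rule_id] = ev.timestamp
        return events


def load_trigger_rules(source) -> list[TriggerRule]:
    """Load and validate a JSON array of trigger rules (path or file object)."""
    if hasattr(source, "read"):
        doc = json.load(source)
    else:
        with open(source) as fh:
            doc = json.load(fh)
    if not isinstance(doc, list):
        raise SchemaError("trigger-rule file must contain a JSON array")
    rules = []
    for i, entry in enumerate(doc):
        try:
            rules.append(
                TriggerRule(
                    rule_id=entry["rule_id"],
                    kind=entry["kind"],
                    predicate=entry.get("predicate", {}),
                    goal_variables=tuple(
                        (g["variable"], g["direction"]) for g in entry["goal_variables"]
                    ),
                    refractory_minutes=float(entry.get("refractory_minutes", 60.0)),
                )
            )
        except KeyError as exc:
            raise SchemaError(f"rule #{i}: missing field {exc}") from None
    ids = [r.rule_id for r in rules]
    if len(ids) != len(set(ids)):
        raise SchemaError("duplicate rule_id in trigger-rule file")
    return rules
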