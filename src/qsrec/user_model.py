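"""Multidimensional quantified-self (QS) user record for a child cohort.

A :class:`UserModel` gathers everything an activity recommender needs to
know about one child: anthropometric history (weight, height, BMI,
skinfolds), a biometric activity log (heart rate, steps, position),
per-session entrance/exit emotions, Mediterranean-diet adherence
(KIDMED-style questionnaire), standardized behavioural scale scores with
at-risk / clinical flags, a gamification player typology (HEXAD), stated
preferences, the socio-economic environment and a weekly schedule.

Records are ingested append-only and in time order; each ingestion
reports which *derived indicators* (BMI, obesity class, sedentary
minutes, diet tier, ...) changed, which is what downstream trigger rules
react to.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta, timezone
from typing import Any, Mapping, Sequence

from .errors import DomainError, MappingError, OrderingError, SchemaError
from .reference import ObesityReferenceTable, classify_obesity, compute_bmi

__all__ = [
    "AnthroRecord",
    "BiometricSample",
    "EmotionRecord",
    "DietProfile",
    "BehavioralProfile",
    "PlayerProfile",
    "UserModel",
    "compute_bmi",
    "classify_obesity",
    "classify_emotion_valence",
    "default_valence_mapping",
    "kidmed_score",
    "hexad_dominant_type",
    "sedentary_minutes",
    "derived_indicators",
    "ingest_record",
    "JUSTIFICATION_CATEGORIES",
    "HEXAD_ORDER",
]

JUSTIFICATION_CATEGORIES = (
    "Person",
    "Structure",
    "Context",
    "Person-Structure",
    "Person-Context",
    "Structure-Context",
    "Person-Structure-Context",
)

# Fixed subscale order; also the tie-break order for the dominant type.
HEXAD_ORDER = ("Philanthropic", "Achiever", "Socializer", "Free spirit", "Player", "Disruptor")

VALENCES = ("positive", "negative", "neutral")


def _ensure_aware(ts: datetime) -> datetime:
    """Timestamps are ISO-8601 with timezone; naive input is taken as UTC."""
    if ts.tzinfo is None:
        return ts.replace(tzinfo=timezone.utc)
    return ts


# ---------------------------------------------------------------------------
# Record types


@dataclass(frozen=True)
class AnthroRecord:
    """One anthropometric measurement session."""

    timestamp: datetime
    age: float  # years, decimal
    sex: str  # "male" | "female"
    weight: float  # kg
    height: float  # m
    bmi: float | None = None  # kg/m^2; derived if omitted
    skinfolds: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "timestamp", _ensure_aware(self.timestamp))
        if not self.weight > 0:
            raise SchemaError(f"weight must be positive, got {self.weight}")
        if not 0.5 < self.height < 2.5:
            raise SchemaError(f"height {self.height} m outside plausible range (0.5, 2.5)")
        if not 0 <= self.age <= 18:
            raise SchemaError(f"age {self.age} outside [0, 18] years")
        if self.sex not in ("male", "female"):
            raise SchemaError(f"sex must be 'male' or 'female', got {self.sex!r}")
        derived = compute_bmi(self.weight, self.height)
        if self.bmi is None:
            object.__setattr__(self, "bmi", derived)
        elif abs(self.bmi - derived) > 1e-9:
            raise SchemaError(
                f"stated bmi {self.bmi} inconsistent with weight/height ({derived:.6f})"
            )


@dataclass(frozen=True)
class BiometricSample:
    """One wearable sample (all channels optional)."""

    timestamp: datetime
    heart_rate: float | None = None  # beats/minute
    steps: int | None = None
    speed: float | None = None  # m/s
    distance: float | None = None  # m
    pace: float | None = None  # s/m
    position: tuple[float, float] | None = None  # (lat, lon), decimal degrees

    def __post_init__(self) -> None:
        object.__setattr__(self, "timestamp", _ensure_aware(self.timestamp))
        if self.heart_rate is not None and not 0 < self.heart_rate <= 250:
            raise SchemaError(f"heart_rate {self.heart_rate} outside (0, 250]")
        for name in ("steps", "distance"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise SchemaError(f"{name} must be non-negative, got {v}")


@dataclass(frozen=True)
class EmotionRecord:
    """Self-reported emotion at the entrance or exit of a session."""

    session_id: str
    moment: str  # "entrance" | "exit"
    emotion: str
    justification: str

    def __post_init__(self) -> None:
        if self.moment not in ("entrance", "exit"):
            raise SchemaError(f"moment must be 'entrance' or 'exit', got {self.moment!r}")
        if self.justification not in JUSTIFICATION_CATEGORIES:
            raise SchemaError(
                f"justification {self.justification!r} not one of {JUSTIFICATION_CATEGORIES}"
            )


def default_valence_mapping() -> dict[str, str]:
    """The shipped 10-label emotion→valence table (a configurable stand-in)."""
    ref = importlib.resources.files("qsrec.data") / "emotion_valence.json"
    return json.loads(ref.read_text())


def classify_emotion_valence(
    record: EmotionRecord | str, mapping: Mapping[str, str] | None = None
) -> str:
    """Map an emotion label to positive / negative / neutral valence."""
    label = record.emotion if isinstance(record, EmotionRecord) else record
    table = mapping if mapping is not None else default_valence_mapping()
    try:
        return table[label]
    except KeyError:
        raise MappingError(f"emotion label {label!r} has no valence mapping") from None


# Default 16-item scheme: 12 items score +1, 4 score -1.
_KIDMED_DEFAULT_WEIGHTS = (1,) * 12 + (-1,) * 4
_KIDMED_DEFAULT_CUTPOINTS = (3, 7)  # score <= 3 low, 4..7 medium, >= 8 high


def kidmed_score(
    answers: Sequence[bool],
    weights: Sequence[int] | None = None,
    cutpoints: tuple[int, int] = _KIDMED_DEFAULT_CUTPOINTS,
) -> tuple[int, str]:
    """Score a Mediterranean-diet adherence questionnaire.

    Each yes-answer contributes its item weight (+1 or -1); the total is
    mapped to a low / medium / high adherence tier by the cutpoints.
    """
    w = tuple(weights) if weights is not None else _KIDMED_DEFAULT_WEIGHTS
    if len(answers) != len(w):
        raise SchemaError(f"{len(answers)} answers but {len(w)} weights")
    score = int(sum(wi for wi, a in zip(w, answers) if a))
    lo, hi = cutpoints
    tier = "low" if score <= lo else ("medium" if score <= hi else "high")
    return score, tier


@dataclass(frozen=True)
class DietProfile:
    """Diet-adherence questionnaire answers with derived score and tier."""

    item_answers: tuple[bool, ...]
    weights: tuple[int, ...] | None = None
    score: int = field(init=False)
    tier: str = field(init=False)

    def __post_init__(self) -> None:
        score, tier = kidmed_score(self.item_answers, self.weights)
        object.__setattr__(self, "item_answers", tuple(self.item_answers))
        object.__setattr__(self, "score", score)
        object.__setattr__(self, "tier", tier)


# Behavioural scales: higher is worse on "difficulty" scales, better on
# "adaptive" scales; standardized (T-like) scores band into risk flags.
_DEFAULT_SCALE_KINDS = {
    "anxiety": "difficulty",
    "depression": "difficulty",
    "social_stress": "difficulty",
    "atypicality": "difficulty",
    "locus_of_control": "difficulty",
    "self_esteem": "adaptive",
    "self_reliance": "adaptive",
    "interpersonal_relations": "adaptive",
}


def _risk_flag(score: float, kind: str) -> str:
    if kind == "difficulty":
        if score >= 70:
            return "clinical"
        if score >= 60:
            return "at_risk"
    elif kind == "adaptive":
        if score <= 30:
            return "clinical"
        if score <= 40:
            return "at_risk"
    else:
        raise SchemaError(f"scale kind must be 'difficulty' or 'adaptive', got {kind!r}")
    return "none"


@dataclass(frozen=True)
class BehavioralProfile:
    """Standardized behavioural scale scores with derived risk flags."""

    scale_scores: Mapping[str, float]
    scale_kinds: Mapping[str, str] = field(default_factory=lambda: dict(_DEFAULT_SCALE_KINDS))
    risk_flags: Mapping[str, str] = field(init=False)

    def __post_init__(self) -> None:
        flags = {}
        for name, score in self.scale_scores.items():
            kind = self.scale_kinds.get(name)
            if kind is None:
                raise SchemaError(f"scale {name!r} has no declared kind")
            flags[name] = _risk_flag(score, kind)
        object.__setattr__(self, "risk_flags", flags)


def hexad_dominant_type(player: "PlayerProfile | Mapping[str, float]") -> str:
    """Dominant gamification user type; ties break by the fixed HEXAD order."""
    scores = player.subscale_scores if isinstance(player, PlayerProfile) else player
    if not scores:
        raise DomainError("no subscale scores")
    rank = {name: i for i, name in enumerate(HEXAD_ORDER)}
    # unknown subscales sort after the canonical six, then alphabetically;
    # a max over (-score, rank) picks the highest score, first-listed on ties
    return min(scores, key=lambda k: (-scores[k], rank.get(k, len(HEXAD_ORDER)), k))


@dataclass(frozen=True)
class PlayerProfile:
    """HEXAD subscale scores with the derived dominant type."""

    subscale_scores: Mapping[str, float]
    dominant_type: str = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "dominant_type", hexad_dominant_type(self.subscale_scores))


def sedentary_minutes(
    log: Sequence[BiometricSample],
    window: tuple[datetime, datetime],
    step_threshold: float = 20.0,
) -> int:
    """Minutes in ``[start, end)`` whose step rate is below the threshold.

    A minute with no samples counts as sedentary (conservative policy:
    absence of movement evidence is treated as inactivity).
    """
    start, end = _ensure_aware(window[0]), _ensure_aware(window[1])
    if not start < end:
        raise DomainError("window start must precede end")
    # steps recorded per sample are attributed to the minute containing it
    per_minute: dict[int, float] = {}
    for sample in log:
        if sample.steps is None:
            continue
        ts = sample.timestamp
        if start <= ts < end:
            k = int((ts - start).total_seconds() // 60)
            per_minute[k] = per_minute.get(k, 0.0) + sample.steps
    n_minutes = int((end - start).total_seconds() // 60)
    return sum(1 for m in range(n_minutes) if per_minute.get(m, 0.0) < step_threshold)


# ---------------------------------------------------------------------------
# The aggregate model


@dataclass(frozen=True)
class UserModel:
    """The full QS record of one child."""

    user_id: str
    anthro_history: tuple[AnthroRecord, ...] = ()
    biometric_log: tuple[BiometricSample, ...] = ()
    emotion_log: tuple[EmotionRecord, ...] = ()
    diet: DietProfile | None = None
    behavior: BehavioralProfile | None = None
    player: PlayerProfile | None = None
    preferences: Mapping[str, Any] = field(default_factory=dict)
    environment: Mapping[str, Any] = field(default_factory=dict)
    schedule: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.user_id:
            raise SchemaError("user_id must be non-empty")
        object.__setattr__(self, "anthro_history", tuple(self.anthro_history))
        object.__setattr__(self, "biometric_log", tuple(self.biometric_log))
        object.__setattr__(self, "emotion_log", tuple(self.emotion_log))
        for hist in (self.anthro_history, self.biometric_log):
            times = [r.timestamp for r in hist]
            if any(b <= a for a, b in zip(times, times[1:])):
                raise OrderingError(f"history of {self.user_id!r} not strictly time-ordered")


def derived_indicators(
    model: UserModel,
    ref: ObesityReferenceTable | None = None,
    now: datetime | None = None,
    sedentary_window_minutes: int = 60,
    step_threshold: float = 20.0,
    valence_mapping: Mapping[str, str] | None = None,
) -> dict[str, Any]:
    """Compute every derived indicator trigger rules can reference.

    The sedentary window is the trailing ``sedentary_window_minutes``
    ending at ``now`` (default: the latest biometric sample).
    """
    out: dict[str, Any] = {}
    if model.anthro_history:
        last = model.anthro_history[-1]
        out["bmi"] = last.bmi
        out["obesity_class"] = classify_obesity(last.sex, last.age, last.bmi, ref)
        out["age"] = last.age
        out["sex"] = last.sex
    if model.biometric_log or now is not None:
        end = _ensure_aware(now) if now is not None else model.biometric_log[-1].timestamp
        start = end - timedelta(minutes=sedentary_window_minutes)
        out["sedentary_minutes"] = sedentary_minutes(
            model.biometric_log, (start, end), step_threshold
        )
    if model.diet is not None:
        out["diet_score"] = model.diet.score
        out["diet_tier"] = model.diet.tier
    if model.player is not None:
        out["player_type"] = model.player.dominant_type
    if model.emotion_log:
        out["last_emotion_valence"] = classify_emotion_valence(
            model.emotion_log[-1], valence_mapping
        )
    return out


def ingest_record(
    model: UserModel,
    record: AnthroRecord | BiometricSample | EmotionRecord | DietProfile | BehavioralProfile | PlayerProfile,
    **indicator_kwargs: Any,
) -> tuple[UserModel, set[str]]:
    """Append a record and report which derived indicators changed.

    Histories are append-only and strictly time-ordered.  Appending an
    exact duplicate of the last record of its kind is a no-op (empty
    change set).  ``indicator_kwargs`` are forwarded to
    :func:`derived_indicators`.
    """
    before = derived_indicators(model, **indicator_kwargs)

    if isinstance(record, AnthroRecord):
        new_model = _append_timed(model, record, "anthro_history")
    elif isinstance(record, BiometricSample):
        new_model = _append_timed(model, record, "biometric_log")
    elif isinstance(record, EmotionRecord):
        if model.emotion_log and model.emotion_log[-1] == record:
            new_model = model
        else:
            new_model = replace(model, emotion_log=model.emotion_log + (record,))
    elif isinstance(record, DietProfile):
        new_model = replace(model, diet=record)
    elif isinstance(record, BehavioralProfile):
        new_model = replace(model, behavior=record)
    elif isinstance(record, PlayerProfile):
        new_model = replace(model, player=record)
    else:
        raise SchemaError(f"unsupported record type {type(record).__name__}")

    after = derived_indicators(new_model, **indicator_kwargs)
    changed = {k for k in set(before) | set(after) if before.get(k) != after.get(k)}
    return new_model, changed


def _append_timed(model: UserModel, record, attr: str) -> UserModel:
    history: tuple = getattr(model, attr)
    if history:
        last = history[-1]
        if last == record:
            return model  # idempotent duplicate
        if record.timestamp <= last.timestamp:
            raise OrderingError(
                f"record at {record.timestamp.isoformat()} not after "
                f"last {attr} entry at {last.timestamp.isoformat()}"
            )
    return replace(model, **{attr: history + (record,)})
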