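"""Synthetic child-cohort simulator and closed-loop harness.

Emulates the study population the recommender was designed for: children
aged 6-12 whose BMI exceeds the obesity reference threshold for their
sex and age, with weekly schedules, home/school locations, per-session
entrance/exit emotions, and *latent* per-category action preferences
that drive stochastic (Bernoulli) reward feedback.  Running the closed
loop exercises the full pipeline — trigger, filter, choose, reward,
learn — with no external data, and reports cumulative reward, cumulative
regret against the latent-preference oracle, and per-child gamification
state (pirate-themed points, missions and islands).
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .bandit import (
    BanditState,
    ContextKey,
    RewardFeedback,
    choose_action,
    cumulative_regret,
    discretize_context,
    update_bandit,
)
from .errors import ConfigurationError
from .planner import Action, WorldState, filter_actions, load_catalog
from .reference import ObesityReferenceTable, classify_obesity, default_reference_table
from .triggers import TriggerEngine, TriggerRule, load_trigger_rules
from .user_model import VALENCES, hexad_dominant_type

__all__ = [
    "SimConfig",
    "SimChild",
    "GamificationState",
    "SimulationResult",
    "DEFAULT_TRANSITION_MATRIX",
    "sample_emotion_transition",
    "generate_cohort",
    "simulate_day",
    "run_closed_loop",
    "award_points",
    "default_catalog",
    "default_rules",
]

# Entrance->exit transition probabilities mirroring the observed session
# percentages: every neutral entrance ends positive; 80% of negative
# entrances end positive (20% neutral); positive entrances stay positive
# 94.4% of the time, turn negative 4.3%, neutral 1.3%.
DEFAULT_TRANSITION_MATRIX: dict[str, dict[str, float]] = {
    "positive": {"positive": 0.944, "negative": 0.043, "neutral": 0.013},
    "negative": {"positive": 0.8, "negative": 0.0, "neutral": 0.2},
    "neutral": {"positive": 1.0, "negative": 0.0, "neutral": 0.0},
}

# Latent per-category reward base means: what fraction of recommendations
# of each kind a typical child in this cohort responds well to.
DEFAULT_CATEGORY_MEANS: dict[str, float] = {
    "physical_activity": 0.6,
    "active_game": 0.8,
    "nutrition_education": 0.45,
    "motivation": 0.55,
    "reminder": 0.35,
}

_HEXAD = ("Philanthropic", "Achiever", "Socializer", "Free spirit", "Player", "Disruptor")


def default_catalog() -> list[Action]:
    ref = importlib.resources.files("qsrec.data") / "default_catalog.json"
    with importlib.resources.as_file(ref) as path:
        return load_catalog(path)


def default_rules() -> list[TriggerRule]:
    ref = importlib.resources.files("qsrec.data") / "default_trigger_rules.json"
    with importlib.resources.as_file(ref) as path:
        return load_trigger_rules(path)


def _validate_matrix(matrix: Mapping[str, Mapping[str, float]]) -> None:
    for row in VALENCES:
        if row not in matrix:
            raise ConfigurationError(f"transition matrix missing row {row!r}")
        total = sum(matrix[row].get(c, 0.0) for c in VALENCES)
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"transition row {row!r} sums to {total}, not 1")
        if any(p < 0 for p in matrix[row].values()):
            raise ConfigurationError(f"transition row {row!r} has negative probability")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a simulated cohort run."""

    n_children: int = 45
    n_days: int = 14
    seed: int = 0
    girls_fraction: float = 25 / 45
    category_means: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_MEANS)
    )
    preference_concentration: float = 5.0
    transition_matrix: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TRANSITION_MATRIX.items()}
    )
    policy: str = "ucb1"
    exploration_constant: float = 1.0
    epsilon: float = 0.1
    points_per_mission: int = 10
    missions_per_island: int = 5
    share_bandit: bool = False
    start_date: str = "2026-01-05"  # a Monday

    def __post_init__(self) -> None:
        if self.n_children < 1:
            raise ConfigurationError(f"n_children must be >= 1, got {self.n_children}")
        if self.n_days < 1:
            raise ConfigurationError(f"n_days must be >= 1, got {self.n_days}")
        _validate_matrix(self.transition_matrix)

    @classmethod
    def from_mapping(cls, doc: Mapping[str, Any]) -> "SimConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)


@dataclass(frozen=True)
class GamificationState:
    """Pirate-themed reward ledger: points, missions, unlocked islands."""

    points: int = 0
    missions_completed: int = 0
    islands_unlocked: int = 0


def award_points(
    state: GamificationState,
    event: Mapping[str, Any],
    points_per_mission: int = 10,
    missions_per_island: int = 5,
) -> GamificationState:
    """Credit a completed recommendation (reward 1) as a mission.

    Every ``missions_per_island``-th mission unlocks a new island.
    """
    if not event.get("reward"):
        return state
    missions = state.missions_completed + 1
    return GamificationState(
        points=state.points + points_per_mission,
        missions_completed=missions,
        islands_unlocked=missions // missions_per_island,
    )


@dataclass
class SimChild:
    """One synthetic cohort member (always obese under the reference table)."""

    child_id: str
    age: float
    sex: str
    height: float
    weight: float
    bmi: float
    player_type: str
    home: tuple[float, float]
    school: tuple[float, float]
    latent_preference: dict[str, float]
    emotion: str
    gamification: GamificationState = field(default_factory=GamificationState)


def generate_cohort(
    config: SimConfig,
    rng: np.random.Generator,
    ref: ObesityReferenceTable | None = None,
) -> list[SimChild]:
    """Sample a cohort satisfying the obesity inclusion criterion.

    Ages uniform on [6, 12]; sex by the configured girls fraction;
    heights around the reference medians; BMI drawn strictly above the
    sex/age obesity threshold so that every child is included.  Latent
    per-category preferences are Beta-distributed around the configured
    base means with the configured concentration.
    """
    ref = ref if ref is not None else default_reference_table()
    kappa = config.preference_concentration
    children = []
    for i in range(config.n_children):
        age = float(rng.uniform(6.0, 12.0))
        sex = "female" if rng.random() < config.girls_fraction else "male"
        height = float(np.clip(rng.normal(1.31, 0.09), 1.05, 1.65))
        threshold = ref.threshold(sex, age)
        bmi = threshold + 0.1 + float(rng.gamma(2.0, 1.0))
        weight = bmi * height**2
        prefs = {}
        for category, base in config.category_means.items():
            if base <= 0.0 or base >= 1.0:
                prefs[category] = float(base)  # degenerate preference, no spread
            else:
                a, b = kappa * base, kappa * (1.0 - base)
                prefs[category] = float(rng.beta(a, b))
        home = (28.46 + float(rng.normal(0, 0.01)), -16.25 + float(rng.normal(0, 0.01)))
        school = (home[0] + float(rng.normal(0, 0.005)), home[1] + float(rng.normal(0, 0.005)))
        emotion = str(rng.choice(VALENCES, p=[0.6, 0.15, 0.25]))
        scores = {t: float(rng.uniform(5, 25)) for t in _HEXAD}
        child = SimChild(
            child_id=f"child_{i:03d}",
            age=age,
            sex=sex,
            height=height,
            weight=weight,
            bmi=bmi,
            player_type=hexad_dominant_type(scores),
            home=home,
            school=school,
            latent_preference=prefs,
            emotion=emotion,
        )
        assert classify_obesity(sex, age, bmi, ref) == "obese"
        children.append(child)
    return children


def sample_emotion_transition(
    current: str,
    moment: str,
    matrix: Mapping[str, Mapping[str, float]],
    rng: np.random.Generator,
) -> str:
    """Draw the next valence from the transition row of the current one."""
    _validate_matrix(matrix)
    if current not in VALENCES:
        raise ConfigurationError(f"unknown valence {current!r}")
    probs = [matrix[current].get(c, 0.0) for c in VALENCES]
    return str(rng.choice(VALENCES, p=probs))


def _session_state(child: SimChild, when: datetime, rng: np.random.Generator) -> WorldState:
    location = "home" if when.weekday() < 5 else "park"
    return WorldState(
        {
            "timestamp": when,
            "location_category": location,
            "sedentary_minutes": int(rng.integers(0, 91)),
            "age": child.age,
            "player_type": child.player_type,
        }
    )


def simulate_day(
    child: SimChild,
    day: datetime,
    engine: TriggerEngine,
    catalog: Sequence[Action],
    bandit: BanditState,
    config: SimConfig,
    rng: np.random.Generator,
) -> list[dict[str, Any]]:
    """Run one child-day through trigger -> filter -> choose -> reward -> learn.

    Mutates ``child`` (emotion state, gamification ledger), ``engine``
    (refractory clock) and ``bandit`` (arm statistics) in place and
    returns the day's event records.
    """
    events: list[dict[str, Any]] = []
    for hour, minute in ((10, 30), (17, 30)):
        now = day.replace(hour=hour, minute=minute)
        fired = engine.poll(now)
        for trig in fired:
            state = _session_state(child, now, rng)
            candidates = filter_actions(catalog, state, trig.goal)
            if not candidates:
                continue
            context = discretize_context(state.assignment)
            action_id = choose_action(bandit, context, candidates)
            chosen = next(a for a in candidates if a.action_id == action_id)
            p = child.latent_preference.get(chosen.category, 0.5)
            reward = float(rng.random() < p)
            entrance = child.emotion
            exit_ = sample_emotion_transition(
                entrance, "exit", config.transition_matrix, rng
            )
            child.emotion = exit_
            update_bandit(bandit, RewardFeedback(context, action_id, reward, now))
            event = {
                "day": day.date().isoformat(),
                "time": now.strftime("%H:%M"),
                "child_id": child.child_id,
                "rule_id": trig.rule_id,
                "context": context.to_string(),
                "candidates": ";".join(a.action_id for a in candidates),
                "action_id": action_id,
                "category": chosen.category,
                "reward": reward,
                "entrance_emotion": entrance,
                "exit_emotion": exit_,
            }
            child.gamification = award_points(
                child.gamification,
                event,
                config.points_per_mission,
                config.missions_per_island,
            )
            events.append(event)
    return events


@dataclass
class SimulationResult:
    events: pd.DataFrame
    metrics: dict[str, Any]
    children: list[SimChild]
    bandits: dict[str, BanditState]


def _oracle_means(
    child: SimChild, events: pd.DataFrame, catalog: Sequence[Action]
) -> dict[str, dict[str, float]]:
    """True per-(context, action) reward means implied by latent preferences."""
    categories = {a.action_id: a.category for a in catalog}
    oracle: dict[str, dict[str, float]] = {}
    sub = events[events["child_id"] == child.child_id]
    for ctx, grp in sub.groupby("context"):
        arm_ids = set()
        for cand in grp["candidates"]:
            arm_ids.update(cand.split(";"))
        oracle[str(ctx)] = {
            aid: child.latent_preference.get(categories[aid], 0.5) for aid in arm_ids
        }
    return oracle


def run_closed_loop(
    config: SimConfig,
    catalog: Sequence[Action] | None = None,
    rules: Sequence[TriggerRule] | None = None,
) -> SimulationResult:
    """Simulate the full cohort and aggregate closed-loop metrics.

    Each child gets an independent bandit (unless ``share_bandit``);
    regret is computed against the oracle that always picks the
    candidate with the highest latent preference in each context.
    """
    catalog = list(catalog) if catalog is not None else default_catalog()
    rules = list(rules) if rules is not None else default_rules()
    master = np.random.default_rng(config.seed)
    cohort_rng = np.random.default_rng(master.integers(2**31))
    children = generate_cohort(config, cohort_rng)

    shared = BanditState(
        exploration_constant=config.exploration_constant,
        rng_seed=int(master.integers(2**31)),
        policy=config.policy,
        epsilon=config.epsilon,
    )
    bandits: dict[str, BanditState] = {}
    all_events: list[dict[str, Any]] = []
    start = datetime.fromisoformat(config.start_date).replace(tzinfo=timezone.utc)
    for child in children:
        rng = np.random.default_rng(master.integers(2**31))
        bandit = shared if config.share_bandit else BanditState(
            exploration_constant=config.exploration_constant,
            rng_seed=int(master.integers(2**31)),
            policy=config.policy,
            epsilon=config.epsilon,
        )
        bandits[child.child_id] = bandit
        engine = TriggerEngine(rules)
        for d in range(config.n_days):
            all_events += simulate_day(
                child, start + timedelta(days=d), engine, catalog, bandit, config, rng
            )

    columns = [
        "day", "time", "child_id", "rule_id", "context", "candidates",
        "action_id", "category", "reward", "entrance_emotion", "exit_emotion",
    ]
    events = pd.DataFrame(all_events, columns=columns)
    events = events.sort_values(["day", "time", "child_id"], kind="stable").reset_index(
        drop=True
    )

    regret = 0.0
    for child in children:
        oracle = _oracle_means(child, events, catalog)
        sub = events[events["child_id"] == child.child_id]
        history = list(zip(sub["context"], sub["action_id"], sub["reward"]))
        regret += cumulative_regret(history, oracle)

    metrics = {
        "n_children": config.n_children,
        "n_days": config.n_days,
        "n_events": int(len(events)),
        "cumulative_reward": float(events["reward"].sum()) if len(events) else 0.0,
        "mean_reward": float(events["reward"].mean()) if len(events) else 0.0,
        "cumulative_regret": float(regret),
        "gamification": {
            c.child_id: {
                "points": c.gamification.points,
                "missions_completed": c.gamification.missions_completed,
                "islands_unlocked": c.gamification.islands_unlocked,
            }
            for c in children
        },
    }
    return SimulationResult(events=events, metrics=metrics, children=children,
                            bandits=bandits)


def write_result(result: SimulationResult, out_dir) -> None:
    """Write the event log (CSV) and metrics (JSON) deterministically."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.events.to_csv(out / "events.csv", index=False, lineterminator="\n")
    (out / "metrics.json").write_text(
        json.dumps(result.metrics, indent=2, sort_keys=True) + "\n"
    )
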