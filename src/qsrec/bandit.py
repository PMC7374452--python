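"""Contextual multi-armed-bandit action chooser.

Given the filtered candidate actions, the chooser picks the one with the
best expected outcome in the current context and learns from reward
feedback, balancing exploration against exploitation so that the number
of mismatched recommendations stays small (sublinear cumulative
regret).  The context is a deliberately coarse key — time-of-day bin,
weekday/weekend, location category and the child's dominant player
type — and each context keeps an independent arm table.

The default strategy is UCB1 (optimistic score mean + c·sqrt(2·ln N /
pulls), untried arms first); an epsilon-greedy strategy is available
behind the same interface.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import datetime
from typing import Any, Mapping, Sequence

import numpy as np

from .errors import DomainError, SchemaError
from .planner import Action, WorldState
from .user_model import UserModel

__all__ = [
    "ContextKey",
    "ArmStats",
    "RewardFeedback",
    "BanditState",
    "discretize_context",
    "choose_action",
    "update_bandit",
    "cumulative_regret",
    "TIME_BINS",
]

# Half-open hour bins: [6,12) morning, [12,18) afternoon, [18,24) evening, [0,6) night.
TIME_BINS = ("morning", "afternoon", "evening", "night")


@dataclass(frozen=True)
class ContextKey:
    time_bin: str
    day_type: str
    location_category: str = "other"
    player_type: str = "other"

    def __post_init__(self) -> None:
        if self.time_bin not in TIME_BINS:
            raise SchemaError(f"unknown time_bin {self.time_bin!r}")
        if self.day_type not in ("weekday", "weekend"):
            raise SchemaError(f"unknown day_type {self.day_type!r}")

    def to_string(self) -> str:
        return "|".join(
            (self.time_bin, self.day_type, self.location_category, self.player_type)
        )

    @classmethod
    def from_string(cls, text: str) -> "ContextKey":
        parts = text.split("|")
        if len(parts) != 4:
            raise SchemaError(f"malformed context key {text!r}")
        return cls(*parts)


def discretize_context(
    state: WorldState | Mapping[str, Any], model: UserModel | None = None
) -> ContextKey:
    """Bucket a world state (and optionally the child's profile) into a context key.

    Expects a ``timestamp`` variable in the state; unknown components
    map to ``"other"``.
    """
    assignment = state.assignment if isinstance(state, WorldState) else state
    ts = assignment.get("timestamp")
    if not isinstance(ts, datetime):
        raise SchemaError("state must carry a datetime under 'timestamp'")
    hour = ts.hour
    if 6 <= hour < 12:
        time_bin = "morning"
    elif 12 <= hour < 18:
        time_bin = "afternoon"
    elif 18 <= hour < 24:
        time_bin = "evening"
    else:
        time_bin = "night"
    day_type = "weekday" if ts.weekday() < 5 else "weekend"
    location = assignment.get("location_category") or "other"
    player = "other"
    if model is not None and model.player is not None:
        player = model.player.dominant_type
    elif "player_type" in assignment:
        player = assignment["player_type"] or "other"
    return ContextKey(time_bin, day_type, str(location), str(player))


@dataclass
class ArmStats:
    pulls: int = 0
    mean_reward: float = 0.0

    def __post_init__(self) -> None:
        if self.pulls < 0:
            raise SchemaError("pulls must be non-negative")
        if self.pulls > 0 and not 0.0 <= self.mean_reward <= 1.0:
            raise SchemaError("mean_reward must lie in [0, 1]")


@dataclass(frozen=True)
class RewardFeedback:
    context: ContextKey
    action_id: str
    reward: float
    timestamp: datetime | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.reward <= 1.0:
            raise DomainError(f"reward {self.reward} outside [0, 1]")


@dataclass
class BanditState:
    """Per-context arm statistics plus the chooser's configuration."""

    exploration_constant: float = 1.0
    rng_seed: int = 0
    policy: str = "ucb1"  # "ucb1" | "epsilon_greedy"
    epsilon: float = 0.1
    table: dict[ContextKey, dict[str, ArmStats]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.exploration_constant <= 0:
            raise SchemaError("exploration_constant must be positive")
        if self.policy not in ("ucb1", "epsilon_greedy"):
            raise SchemaError(f"unknown policy {self.policy!r}")
        self._rng = np.random.default_rng(self.rng_seed)

    def arms(self, context: ContextKey) -> dict[str, ArmStats]:
        return self.table.setdefault(context, {})

    # -- persistence ------------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "exploration_constant": self.exploration_constant,
            "rng_seed": self.rng_seed,
            "policy": self.policy,
            "epsilon": self.epsilon,
            "table": {
                ctx.to_string(): {
                    aid: {"pulls": st.pulls, "mean_reward": st.mean_reward}
                    for aid, st in sorted(arms.items())
                }
                for ctx, arms in sorted(self.table.items(), key=lambda kv: kv[0].to_string())
            },
        }
        return json.dumps(doc, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "BanditState":
        doc = json.loads(text)
        state = cls(
            exploration_constant=doc["exploration_constant"],
            rng_seed=doc["rng_seed"],
            policy=doc.get("policy", "ucb1"),
            epsilon=doc.get("epsilon", 0.1),
        )
        for ctx_text, arms in doc.get("table", {}).items():
            ctx = ContextKey.from_string(ctx_text)
            state.table[ctx] = {
                aid: ArmStats(pulls=st["pulls"], mean_reward=st["mean_reward"])
                for aid, st in arms.items()
            }
        return state


def _candidate_ids(candidates: Sequence[Action | str]) -> list[str]:
    ids = sorted(a.action_id if isinstance(a, Action) else a for a in candidates)
    if not ids:
        raise DomainError("candidate list must be non-empty")
    return ids


def choose_action(
    bandit: BanditState, context: ContextKey, candidates: Sequence[Action | str]
) -> str:
    """Pick one candidate action id for this context.

    UCB1: any untried candidate is chosen first (lexicographically
    smallest); otherwise the candidate maximizing
    mean + c*sqrt(2*ln(N)/pulls), N the total pulls over the candidates
    in this context, ties to the smallest action id.
    """
    ids = _candidate_ids(candidates)
    arms = bandit.arms(context)
    untried = [aid for aid in ids if arms.get(aid) is None or arms[aid].pulls == 0]

    if bandit.policy == "epsilon_greedy":
        if bandit._rng.random() < bandit.epsilon:
            return ids[int(bandit._rng.integers(len(ids)))]
        if untried:
            return untried[0]
        return _argmax_smallest_id(ids, lambda aid: arms[aid].mean_reward)

    if untried:
        return untried[0]
    total = sum(arms[aid].pulls for aid in ids)
    c = bandit.exploration_constant

    def ucb(aid: str) -> float:
        st = arms[aid]
        return st.mean_reward + c * math.sqrt(2.0 * math.log(total) / st.pulls)

    return _argmax_smallest_id(ids, ucb)


def _argmax_smallest_id(ids: Sequence[str], score) -> str:
    """Argmax over sorted ids; exact score ties break to the smallest id."""
    best = max(score(aid) for aid in ids)
    return next(aid for aid in ids if score(aid) == best)


def update_bandit(bandit: BanditState, feedback: RewardFeedback) -> BanditState:
    """Incorporate one reward observation (incremental running mean)."""
    arms = bandit.arms(feedback.context)
    st = arms.setdefault(feedback.action_id, ArmStats())
    st.pulls += 1
    st.mean_reward += (feedback.reward - st.mean_reward) / st.pulls
    return bandit


def replay_feedback(bandit: BanditState, feedback: Sequence[RewardFeedback]) -> BanditState:
    """Rebuild arm statistics from an event log (identical to live updates)."""
    for fb in feedback:
        update_bandit(bandit, fb)
    return bandit


def run_bernoulli_testbed(
    arm_means: Sequence[float],
    rounds: int,
    n_replicates: int = 20,
    seed: int = 0,
    policy: str = "ucb1",
    exploration_constant: float = 1.0,
    epsilon: float = 0.1,
    checkpoints: Sequence[int] = (),
) -> dict[str, Any]:
    """Benchmark a chooser on stationary Bernoulli arms.

    Runs ``n_replicates`` independent replicates of ``rounds`` pulls on
    arms with the given true means (a single context), recording the
    final mean reward and the cumulative regret at each checkpoint.
    ``policy="uniform"`` picks arms uniformly at random, as a baseline.
    Returns per-replicate arrays plus replicate averages.
    """
    if not checkpoints:
        checkpoints = (rounds,)
    context = ContextKey("afternoon", "weekday")
    ids = [f"arm_{i}" for i in range(len(arm_means))]
    means = dict(zip(ids, (float(m) for m in arm_means)))
    best = max(means.values())
    master = np.random.default_rng(seed)
    regret_at = {cp: [] for cp in checkpoints}
    final_rewards = []
    for _ in range(n_replicates):
        rng = np.random.default_rng(master.integers(2**31))
        bandit = BanditState(
            exploration_constant=exploration_constant,
            rng_seed=int(master.integers(2**31)),
            policy="ucb1" if policy == "uniform" else policy,
            epsilon=epsilon,
        )
        regret, total_reward = 0.0, 0.0
        for t in range(1, rounds + 1):
            if policy == "uniform":
                aid = ids[int(rng.integers(len(ids)))]
            else:
                aid = choose_action(bandit, context, ids)
            reward = float(rng.random() < means[aid])
            update_bandit(bandit, RewardFeedback(context, aid, reward))
            regret += best - means[aid]
            total_reward += reward
            if t in regret_at:
                regret_at[t].append(regret)
        final_rewards.append(total_reward / rounds)
    return {
        "regret_at": {cp: np.array(v) for cp, v in regret_at.items()},
        "mean_regret_at": {cp: float(np.mean(v)) for cp, v in regret_at.items()},
        "final_rewards": np.array(final_rewards),
        "mean_final_reward": float(np.mean(final_rewards)),
    }


def cumulative_regret(
    history: Sequence[tuple[Any, str, float]],
    oracle_means: Mapping[Any, Mapping[str, float]] | Mapping[str, float],
) -> float:
    """Sum over steps of (best oracle mean in context - chosen arm's oracle mean).

    ``oracle_means`` maps context -> {action_id: true mean}; a flat
    {action_id: mean} map is accepted for context-free histories.
    """
    total = 0.0
    for context, action_id, _reward in history:
        means = oracle_means
        if means and not isinstance(next(iter(means.values())), (int, float)):
            try:
                means = oracle_means[context]
            except KeyError:
                raise DomainError(f"no oracle means for context {context!r}") from None
        if action_id not in means:
            raise DomainError(f"no oracle mean for action {action_id!r}")
        total += max(means.values()) - means[action_id]
    return total
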