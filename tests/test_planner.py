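import itertools

import numpy as np
import pytest

from qsrec.errors import DomainError, EvaluationError, SchemaError
from qsrec.planner import (
    Action,
    BinaryClause,
    Effect,
    Plan,
    WorldState,
    apply_effects,
    build_plans,
    clause_satisfied,
    filter_actions,
    plan_is_valid,
    preconditions_met,
    validate_catalog,
)
from qsrec.triggers import TriggerGoal


def brute_force_plans(catalog, state, goal, max_len):
    """Independent oracle: replay every sequence of distinct actions."""
    from qsrec.planner import DIRECTION_COMPAT

    def covers(actions):
        return all(
            any(
                e.variable == var and e.operation in DIRECTION_COMPAT[direction]
                for a in actions
                for e in a.goals
            )
            for var, direction in goal.targets
        )

    plans = []
    for length in range(1, max_len + 1):
        for seq in itertools.permutations(catalog, length):
            current = state
            ok = True
            for action in seq:
                if not preconditions_met(action, current):
                    ok = False
                    break
                current = apply_effects(current, action)
            if ok and covers(seq):
                plans.append(tuple(a.action_id for a in seq))
    return sorted(plans, key=lambda ids: (len(ids), ids))


class TestClauseSatisfied:
    @pytest.mark.parametrize(
        "clause,state,expected",
        [
            (BinaryClause("sedentary_minutes", "ge", 60), {"sedentary_minutes": 60}, True),
            (BinaryClause("location_category", "eq", "park"), {"location_category": "school"}, False),
            (BinaryClause("age", "in_set", set(range(6, 13))), {}, False),
            (BinaryClause("age", "in_set", set(range(6, 13))), {"age": 8}, True),
            (BinaryClause("x", "ne", 3), {"x": 4}, True),
            (BinaryClause("x", "lt", 3), {"x": 3}, False),
        ],
    )
    def test_evaluation(self, clause, state, expected):
        assert clause_satisfied(clause, WorldState(state)) is expected

    def test_type_incompatible_comparison_names_variable(self):
        clause = BinaryClause("age", "lt", 10)
        with pytest.raises(EvaluationError, match="age"):
            clause_satisfied(clause, WorldState({"age": "eight"}))


class TestApplyEffects:
    def make(self, *effects):
        return Action("a", "physical_activity", goals=tuple(effects))

    def test_set_creates_variable(self):
        state = apply_effects(WorldState({}), self.make(Effect("warmed_up", "set", True)))
        assert state["warmed_up"] is True

    def test_increase(self):
        state = apply_effects(
            WorldState({"energy_spent": 100}), self.make(Effect("energy_spent", "increase", 50))
        )
        assert state["energy_spent"] == 150

    def test_last_write_wins(self):
        action = self.make(Effect("x", "set", 1), Effect("x", "set", 2))
        assert apply_effects(WorldState({}), action)["x"] == 2

    def test_input_state_unchanged(self):
        original = WorldState({"x": 1})
        apply_effects(original, self.make(Effect("x", "set", 9)))
        assert original["x"] == 1

    def test_increase_on_non_numeric_rejected(self):
        with pytest.raises(EvaluationError):
            apply_effects(WorldState({"x": "hi"}), self.make(Effect("x", "increase", 1)))


class TestFilterActions:
    GOAL = TriggerGoal(targets=(("physical_activity", "increase"),))

    def test_vacuous_preconditions_included(self):
        action = Action("a", "physical_activity",
                        goals=(Effect("physical_activity", "increase", 10),))
        assert filter_actions([action], WorldState({}), self.GOAL) == [action]

    def test_goal_irrelevant_action_excluded(self):
        action = Action("a", "nutrition_education",
                        goals=(Effect("nutrition_knowledge", "increase", 1),))
        assert filter_actions([action], WorldState({}), self.GOAL) == []

    def test_failed_precondition_excluded(self):
        action = Action("a", "physical_activity",
                        preconditions=(BinaryClause("age", "ge", 6),),
                        goals=(Effect("physical_activity", "increase", 10),))
        assert filter_actions([action], WorldState({}), self.GOAL) == []

    def test_exhaustive_check_on_toy_catalog(self):
        """The filter equals a literal clause-by-clause check of all 5 actions."""
        state = WorldState({"sedentary_minutes": 45, "location_category": "home"})
        catalog = [
            Action(f"a{i}", "physical_activity",
                   preconditions=(BinaryClause("sedentary_minutes", "ge", 10 * i),),
                   goals=(Effect("physical_activity", "increase", 10),))
            for i in range(1, 6)
        ]
        expected = [
            a for a in catalog
            if all(clause_satisfied(c, state) for c in a.preconditions)
        ]
        assert filter_actions(catalog, state, self.GOAL) == expected

    def test_monotone_in_preconditions(self):
        """Removing a clause from an action never removes it from the result."""
        state = WorldState({"sedentary_minutes": 45})
        strict = Action("a", "physical_activity",
                        preconditions=(BinaryClause("sedentary_minutes", "ge", 30),
                                       BinaryClause("age", "ge", 6)),
                        goals=(Effect("physical_activity", "increase", 10),))
        relaxed = Action("a", "physical_activity",
                         preconditions=strict.preconditions[:1],
                         goals=strict.goals)
        if filter_actions([strict], state, self.GOAL):
            assert filter_actions([relaxed], state, self.GOAL)


class TestBuildPlans:
    def test_single_step_plan_for_reachable_goal(self, activity_goal):
        action = Action("solo", "physical_activity",
                        goals=(Effect("activity_done", "set", True),))
        plans = build_plans([action], WorldState({}), activity_goal, max_len=2)
        assert [p.action_ids() for p in plans] == [("solo",)]

    def test_warmup_chain_found_and_shortcut_absent(
        self, warmup_catalog, activity_goal, empty_state
    ):
        plans = build_plans(warmup_catalog, empty_state, activity_goal, max_len=2)
        ids = [p.action_ids() for p in plans]
        assert ("a_warmup", "b_activity") in ids
        assert ("b_activity",) not in ids
        assert ids == brute_force_plans(warmup_catalog, empty_state, activity_goal, 2)

    def test_unreachable_goal_yields_no_plans(self, empty_state):
        goal = TriggerGoal(targets=(("unicorns", "increase"),))
        action = Action("a", "motivation", goals=(Effect("motivation", "increase", 1),))
        assert build_plans([action], empty_state, goal, max_len=3) == []

    def test_max_len_below_one_rejected(self, warmup_catalog, activity_goal, empty_state):
        with pytest.raises(DomainError):
            build_plans(warmup_catalog, empty_state, activity_goal, max_len=0)

    def test_every_plan_survives_independent_replay(self, empty_state, activity_goal):
        catalog = _random_catalog(np.random.default_rng(7), n_actions=6)
        for plan in build_plans(catalog, empty_state, activity_goal, max_len=3):
            assert plan_is_valid(plan, empty_state)

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_brute_force_on_random_catalogs(self, seed):
        rng = np.random.default_rng(seed)
        catalog = _random_catalog(rng, n_actions=int(rng.integers(2, 7)))
        state = _random_state(rng)
        goal = TriggerGoal(targets=(("goal_var", "increase"),))
        max_len = int(rng.integers(1, 4))
        got = [p.action_ids() for p in build_plans(catalog, state, goal, max_len)]
        assert got == brute_force_plans(catalog, state, goal, max_len)


_VARS = ["v0", "v1", "v2", "goal_var"]


def _random_catalog(rng: np.random.Generator, n_actions: int) -> list[Action]:
    actions = []
    for i in range(n_actions):
        pres = tuple(
            BinaryClause(
                _VARS[int(rng.integers(len(_VARS)))],
                str(rng.choice(["ge", "le", "eq"])),
                int(rng.integers(0, 3)),
            )
            for _ in range(int(rng.integers(0, 3)))
        )
        effs = tuple(
            Effect(
                _VARS[int(rng.integers(len(_VARS)))],
                str(rng.choice(["set", "increase"])),
                int(rng.integers(0, 3)),
            )
            for _ in range(int(rng.integers(1, 3)))
        )
        actions.append(Action(f"act_{i}", "physical_activity", pres, effs))
    return actions


def _random_state(rng: np.random.Generator) -> WorldState:
    return WorldState({v: int(rng.integers(0, 3)) for v in _VARS if rng.random() < 0.7})


class TestValidateCatalog:
    def doc(self, actions):
        return {"variables": {"x": "number", "done": "boolean"}, "actions": actions}

    def entry(self, aid="a1", **overrides):
        base = {
            "action_id": aid,
            "category": "motivation",
            "preconditions": [{"variable": "x", "comparator": "ge", "value": 1}],
            "goals": [{"variable": "done", "operation": "set", "value": True}],
        }
        base.update(overrides)
        return base

    def test_well_formed_catalog_has_no_errors(self):
        actions, errors = validate_catalog(self.doc([self.entry()]))
        assert errors == [] and len(actions) == 1

    def test_duplicate_action_id_names_both_entries(self):
        _, errors = validate_catalog(self.doc([self.entry(), self.entry()]))
        assert any("duplicate" in e and "a1" in e for e in errors)

    def test_undeclared_variable_named(self):
        entry = self.entry(
            preconditions=[{"variable": "mystery", "comparator": "ge", "value": 1}]
        )
        _, errors = validate_catalog(self.doc([entry]))
        assert any("mystery" in e for e in errors)

    def test_type_incompatible_value_reported(self):
        entry = self.entry(
            preconditions=[{"variable": "x", "comparator": "ge", "value": "high"}]
        )
        _, errors = validate_catalog(self.doc([entry]))
        assert any("incompatible" in e for e in errors)

    def test_empty_goals_reported(self):
        _, errors = validate_catalog(self.doc([self.entry(goals=[])]))
        assert any("goals" in e for e in errors)

    def test_shipped_default_catalog_is_valid(self):
        from qsrec.simulate import default_catalog

        catalog = default_catalog()
        assert len(catalog) == 5
        assert [a.action_id for a in catalog] == sorted(a.action_id for a in catalog)
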