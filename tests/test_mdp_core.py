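import itertools
import logging

import numpy as np
import pytest

from micromdp import (
    MDPModel,
    PerturbationSchema,
    RewardVector,
    TransitionCounts,
    TransitionTable,
    build_mdp,
    build_reward,
    combine_actions,
    count_triples,
    discretize_perturbation,
    estimate_transition_table,
    extract_triples,
    generate_cohort,
    policy_value,
    true_state_assignment,
    value_iteration,
)
from micromdp.state_space import UtilityVector


# ---------------------------------------------------------------------------
# Actions
# ---------------------------------------------------------------------------

MILK_SCHEMA = PerturbationSchema(
    name="milk", kind="discretized", levels=["low", "med", "high"], bin_edges=[10, 50]
)


class TestDiscretize:
    def test_milk_volumes_with_zero_merged_into_low(self):
        # 0% category merged into low (<10%); bins [10, 50) left-closed
        assert discretize_perturbation([0, 5, 30, 80], MILK_SCHEMA) == [
            "low", "low", "med", "high",
        ]

    def test_boundary_left_closed(self):
        assert discretize_perturbation([10], MILK_SCHEMA) == ["med"]
        assert discretize_perturbation([9.999], MILK_SCHEMA) == ["low"]
        assert discretize_perturbation([50], MILK_SCHEMA) == ["high"]

    def test_binary_identity(self):
        schema = PerturbationSchema(name="abx", kind="binary", levels=["no", "yes"])
        assert discretize_perturbation(["yes", "no"], schema) == ["yes", "no"]

    def test_unknown_nominal_value_errors(self):
        schema = PerturbationSchema(name="abx", kind="binary", levels=["no", "yes"])
        with pytest.raises(ValueError, match="maybe"):
            discretize_perturbation(["maybe"], schema)


class TestCombineActions:
    def test_two_binary_gives_four_combined(self):
        salmonella = PerturbationSchema(name="salmonella", kind="binary", levels=["s", "c"])
        probiotic = PerturbationSchema(name="probiotic", kind="binary", levels=["p", "c"])
        combined = combine_actions([salmonella, probiotic])
        assert sorted(combined.levels) == ["cc", "cp", "sc", "sp"]
        assert combined.kind == "nominal"

    def test_single_schema_passthrough(self):
        s = PerturbationSchema(name="x", kind="binary", levels=["a", "b"])
        assert combine_actions([s]) is s

    def test_eight_binary_schemas_warn_at_256(self, caplog):
        schemas = [
            PerturbationSchema(name=f"p{i}", kind="binary", levels=[f"y{i}", f"n{i}"])
            for i in range(8)
        ]
        with caplog.at_level(logging.WARNING, logger="micromdp"):
            combined = combine_actions(schemas, joiner="|")
        assert len(combined.levels) == 2**8
        assert any("256" in rec.message for rec in caplog.records)


# ---------------------------------------------------------------------------
# Triples
# ---------------------------------------------------------------------------

class TestExtractTriples:
    def test_consecutive_pairs_forced_by_definition(self, small_dataset):
        from micromdp import assign_states_external

        asg = assign_states_external(small_dataset, "cst")
        triples = extract_triples(small_dataset, asg, "drug")
        # p1: (low,yes,high), (high,yes,high); p2: (low,no,high)
        got = set(
            triples.triples[["from_state", "action", "to_state"]].itertuples(
                index=False, name=None
            )
        )
        assert got == {("low", "yes", "high"), ("high", "yes", "high"), ("low", "no", "high")}

    def test_single_sample_subject_contributes_nothing(self, small_dataset):
        from micromdp import assign_states_external

        ds = small_dataset
        ds.metadata = ds.metadata[ds.metadata["sample_id"] != "p2_t1"].reset_index(drop=True)
        from dataclasses import replace

        ds.abundance = replace(
            ds.abundance, data=ds.abundance.data.drop(index="p2_t1")
        )
        asg = assign_states_external(ds, "cst")
        triples = extract_triples(ds, asg, "drug")
        assert set(triples.triples["subject_id"]) == {"p1"}

    def test_cohort_triple_count_equals_sum_of_intervals(self, two_state_spec):
        ds, _ = generate_cohort(two_state_spec)
        asg = true_state_assignment(ds)
        triples = extract_triples(
            ds, asg, "treatment", action_timing="subject_constant"
        )
        expected = sum(
            len(ds.subject_samples(s)) - 1 for s in ds.subjects
        )
        assert len(triples) == expected == 24 * 5

    def test_missing_action_interval_skipped(self, small_dataset):
        from micromdp import assign_states_external

        small_dataset.metadata.loc[0, "drug"] = None
        asg = assign_states_external(small_dataset, "cst")
        schema = small_dataset.perturbation_schemas[0]
        triples = extract_triples(small_dataset, asg, "drug", schema=schema)
        assert triples.skipped == 1
        assert len(triples) == 2


# ---------------------------------------------------------------------------
# Transition estimation
# ---------------------------------------------------------------------------

class TestEstimateTransitionTable:
    def test_counts_over_row_sums(self):
        counts = np.zeros((2, 1, 2), dtype=int)
        counts[0, 0] = [1, 3]
        counts[1, 0] = [0, 2]
        tc = TransitionCounts(["s1", "s2"], ["a"], counts)
        table = estimate_transition_table(tc)
        np.testing.assert_allclose(table.probs[0, 0], [0.25, 0.75])
        np.testing.assert_allclose(table.probs[1, 0], [0.0, 1.0])
        assert table.observed_mask.all()

    def test_unobserved_self_loop(self):
        counts = np.zeros((2, 2, 2), dtype=int)
        counts[0, 0] = [1, 1]
        counts[1, 0] = [0, 5]
        counts[1, 1] = [2, 2]
        tc = TransitionCounts(["s1", "s2"], ["a", "b"], counts)
        table = estimate_transition_table(tc, unobserved_policy="self_loop")
        np.testing.assert_allclose(table.probs[0, 1], [1.0, 0.0])  # s1 self-loop
        assert not table.observed_mask[0, 1]

    def test_unobserved_uniform(self):
        counts = np.zeros((3, 1, 3), dtype=int)
        counts[0, 0] = [1, 0, 0]
        counts[2, 0] = [0, 0, 1]
        tc = TransitionCounts(list("xyz"), ["a"], counts)
        table = estimate_transition_table(tc, unobserved_policy="uniform")
        np.testing.assert_allclose(table.probs[1, 0], [1 / 3] * 3)

    def test_rows_sum_to_one_and_counts_recoverable(self, two_state_spec):
        ds, _ = generate_cohort(two_state_spec)
        asg = true_state_assignment(ds)
        triples = extract_triples(ds, asg, "treatment", action_timing="subject_constant")
        tc = count_triples(triples, asg.states, ["a", "b"])
        table = estimate_transition_table(tc)
        np.testing.assert_allclose(table.probs.sum(axis=2), 1.0, atol=1e-12)
        row_sums = tc.counts.sum(axis=2)
        recovered = table.probs * row_sums[:, :, None]
        observed = table.observed_mask
        np.testing.assert_allclose(recovered[observed], tc.counts[observed])


# ---------------------------------------------------------------------------
# Rewards
# ---------------------------------------------------------------------------

class TestBuildReward:
    U = UtilityVector(values={"A": 1.0, "B": 2.0, "C": 3.0})

    def test_best_is_indicator_of_argmax(self):
        r = build_reward(self.U, "best")
        assert r.as_dict() == {"A": 0.0, "B": 0.0, "C": 1.0}

    def test_not_worst_excludes_argmin(self):
        r = build_reward(self.U, "not_worst")
        assert r.as_dict() == {"A": 0.0, "B": 1.0, "C": 1.0}

    def test_tied_maximum_errors(self):
        tied = UtilityVector(values={"A": 3.0, "B": 3.0, "C": 1.0})
        with pytest.raises(ValueError, match="tied"):
            build_reward(tied, "best")


# ---------------------------------------------------------------------------
# Value iteration
# ---------------------------------------------------------------------------

def _toy_model():
    """2 states; a1 moves s1→s2 surely, a2 self-loops; s2 absorbing, R(s2)=1."""
    probs = np.zeros((2, 2, 2))
    probs[0, 0] = [0, 1]
    probs[0, 1] = [1, 0]
    probs[1, :] = [0, 1]
    table = TransitionTable(["s1", "s2"], ["a1", "a2"], probs, np.ones((2, 2), bool))
    reward = RewardVector(["s1", "s2"], np.array([0.0, 1.0]), "best")
    return MDPModel(["s1", "s2"], ["a1", "a2"], table, reward, discount=0.9)


class TestValueIteration:
    def test_closed_form_geometric_series(self):
        policy = value_iteration(_toy_model(), epsilon=1e-10)
        assert policy["s1"] == "a1"
        # V(s2) = R(s2) / (1 - gamma) = 10
        assert policy.values["s2"] == pytest.approx(10.0, abs=1e-6)
        assert policy.values["s1"] == pytest.approx(0.9 * 10.0, abs=1e-6)

    def test_zero_reward_gives_zero_values_and_first_action(self):
        model = _toy_model()
        model.reward.values[:] = 0.0
        policy = value_iteration(model)
        assert all(v == pytest.approx(0.0) for v in policy.values.values())
        assert policy["s1"] == "a1" and policy["s2"] == "a1"  # lowest-index tie-break

    def test_policy_invariant_to_reward_scaling_and_shift(self):
        model = _toy_model()
        base = value_iteration(model, epsilon=1e-10).mapping
        for transform in (lambda r: 7.0 * r, lambda r: r + 3.0):
            m2 = _toy_model()
            m2.reward.values = transform(m2.reward.values)
            assert value_iteration(m2, epsilon=1e-10).mapping == base

    def test_fixed_point_residual_below_epsilon(self):
        model = _toy_model()
        eps = 1e-8
        policy = value_iteration(model, epsilon=eps)
        idx = policy.action_indices()
        V = np.array([policy.values[s] for s in model.states])
        T_pi = model.transition.probs[np.arange(2), idx, :]
        residual = np.abs(V - (model.reward.values + 0.9 * T_pi @ V)).max()
        assert residual < eps

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_policy_enumeration(self, seed):
        """Greedy VI policy ties the best of all 3^4 deterministic policies
        evaluated exactly by solving the linear policy-evaluation system."""
        rng = np.random.default_rng(seed)
        n_s, n_a, gamma = 4, 3, 0.9
        probs = rng.dirichlet(np.ones(n_s), size=(n_s, n_a))
        reward = RewardVector(
            [f"s{i}" for i in range(n_s)], rng.random(n_s), "best"
        )
        table = TransitionTable(
            reward.states, [f"a{j}" for j in range(n_a)], probs, np.ones((n_s, n_a), bool)
        )
        model = MDPModel(reward.states, table.actions, table, reward, gamma)
        vi_policy = value_iteration(model, epsilon=1e-10)

        best_value = None
        for combo in itertools.product(range(n_a), repeat=n_s):
            v = policy_value(model, np.array(combo))
            if best_value is None:
                best_value = v
            else:
                best_value = np.maximum(best_value, v)
        vi_value = policy_value(model, vi_policy.action_indices())
        np.testing.assert_allclose(vi_value, best_value, atol=1e-6)

    def test_invalid_discount_rejected(self):
        model = _toy_model()
        with pytest.raises(ValueError, match="discount"):
            MDPModel(model.states, model.actions, model.transition, model.reward, 1.0)
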