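"""Policy reliability: Dirichlet-resampling stability and LOOCV generality.

Transition probabilities are multinomial estimates from (often few)
observed triples, so the optimal policy inherits their uncertainty. Two
complementary checks quantify it:

*Stability* — the posterior of each transition row under a multinomial
likelihood is a Dirichlet with parameters equal to the observed counts
(plus an optional pseudocount where rows contain zeros). We resample many
transition tables from these Dirichlets, re-solve each by value iteration,
and report the fraction of per-state actions that agree with the reference
optimal policy. A ratio near 1 means the recommendation survives estimation
noise; the floor for a completely uninformative table is 1/|A|.

*Generality* — leave-one-subject-out cross-validation. For each subject, a
policy is trained on everyone else; the held-out subject's observed
transitions are bucketed by whether the taken action matched that policy
(following vs not following) and whether the landing state was better,
equal or worse by utility. Policies generalise if same-or-better transitions
are more frequent when the policy was followed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .io_preprocess import LongitudinalDataset
from .mdp_core import (
    MDPModel,
    PerturbationSchema,
    Policy,
    RewardVector,
    TransitionCounts,
    TransitionTable,
    build_mdp,
    count_triples,
    extract_triples,
    value_iteration,
)
from .state_space import StateAssignment, UtilityVector

logger = logging.getLogger("micromdp")

TRANSITION_CATEGORIES = ("better", "equal", "worse")


# ---------------------------------------------------------------------------
# Dirichlet resampling of the transition table
# ---------------------------------------------------------------------------

def sample_posterior_tables(
    counts: TransitionCounts,
    n: int,
    seed: int,
    prior_pseudocount: float = 0.5,
) -> list[TransitionTable]:
    """Draw n transition tables from the per-row Dirichlet posteriors.

    Each (s, a) row is sampled from Dirichlet(counts(s, a, ·) + prior),
    where the pseudocount is added only to rows that contain a zero count —
    rows with all-positive counts use the raw counts, so the hyper-parameters
    coincide with the observed counts wherever that is well defined. A row
    of all zeros with ``prior_pseudocount=0`` is an error (the Dirichlet is
    undefined there).
    """
    if n < 1:
        raise ValueError("need n >= 1 samples")
    if prior_pseudocount < 0:
        raise ValueError("prior_pseudocount must be >= 0")
    c = counts.counts.astype(float)
    n_s, n_a, _ = c.shape
    has_zero = (c == 0).any(axis=2)
    if prior_pseudocount == 0 and (c.sum(axis=2) == 0).any():
        bad = np.argwhere(c.sum(axis=2) == 0)[0]
        raise ValueError(
            f"row (state={counts.states[bad[0]]!r}, action={counts.actions[bad[1]]!r}) "
            "has no observations; a positive prior_pseudocount is required"
        )
    alphas = c.copy()
    if prior_pseudocount > 0 and has_zero.any():
        alphas[has_zero] += prior_pseudocount
        logger.debug(
            "sample_posterior_tables: pseudocount %.3g applied to %d/%d rows containing zeros",
            prior_pseudocount, int(has_zero.sum()), n_s * n_a,
        )
    rng = np.random.default_rng(seed)
    tables = []
    flat = alphas.reshape(n_s * n_a, -1)
    draws = np.stack([rng.dirichlet(row, size=n) for row in flat], axis=1)  # (n, S*A, S)
    observed = c.sum(axis=2) > 0
    for i in range(n):
        probs = draws[i].reshape(n_s, n_a, n_s)
        tables.append(TransitionTable(counts.states, counts.actions, probs, observed))
    return tables


@dataclass
class StabilityReport:
    """Per-state and aggregate agreement with the reference optimal policy."""

    aggregate_ratio: float
    per_state: dict[str, dict[str, float]]  # state -> action -> fraction of resamples
    n_samples: int
    seed: int
    reference_policy: Policy

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "state": s,
                "action": a,
                "ratio": ratio,
                "is_optimal": a == self.reference_policy[s],
            }
            for s, per_action in self.per_state.items()
            for a, ratio in per_action.items()
        ]
        return pd.DataFrame(rows)


def policy_stability(
    counts: TransitionCounts,
    reward: RewardVector,
    discount: float = 0.9,
    n: int = 1000,
    seed: int = 0,
    prior_pseudocount: float = 0.5,
    epsilon: float = 1e-6,
    unobserved_policy: Literal["self_loop", "uniform"] = "self_loop",
) -> StabilityReport:
    """Stability ratio of the optimal policy under transition uncertainty.

    The reference policy is solved on the point-estimate table. Each of the
    n resampled tables is solved the same way; ``per_state[s][a]`` is the
    fraction of resampled policies choosing action a in state s, and the
    aggregate ratio is the mean over states of the reference action's
    fraction (equivalently, the mean over resamples of the per-policy
    agreement fraction).
    """
    reference_model = build_mdp(counts, reward, discount, unobserved_policy)
    reference = value_iteration(reference_model, epsilon)
    ref_idx = reference.action_indices()

    tables = sample_posterior_tables(counts, n, seed, prior_pseudocount)
    n_s, n_a = len(counts.states), len(counts.actions)
    choice_counts = np.zeros((n_s, n_a), dtype=np.int64)
    for table in tables:
        model = MDPModel(counts.states, counts.actions, table, reward, discount)
        pol = value_iteration(model, epsilon)
        choice_counts[np.arange(n_s), pol.action_indices()] += 1
    fractions = choice_counts / n
    aggregate = float(fractions[np.arange(n_s), ref_idx].mean())
    per_state = {
        s: {a: float(fractions[i, j]) for j, a in enumerate(counts.actions)}
        for i, s in enumerate(counts.states)
    }
    return StabilityReport(aggregate, per_state, n, seed, reference)


# ---------------------------------------------------------------------------
# LOOCV generality
# ---------------------------------------------------------------------------

def classify_transition(from_state: str, to_state: str, utility: UtilityVector) -> str:
    """Label a transition better/equal/worse by the utility of the landing state."""
    for s in (from_state, to_state):
        if s not in utility.values:
            raise ValueError(f"state {s!r} has no utility")
    u_from, u_to = utility[from_state], utility[to_state]
    if u_to > u_from:
        return "better"
    if u_to == u_from:
        return "equal"
    return "worse"


@dataclass
class GeneralityReport:
    """LOOCV counts/frequencies of better/equal/worse by policy compliance."""

    counts: dict[str, dict[str, int]]  # {following, not_following} -> category -> n
    unscored: int  # transitions from states unseen in the training fold
    per_subject: pd.DataFrame | None = None

    @property
    def frequencies(self) -> dict[str, dict[str, float]]:
        out: dict[str, dict[str, float]] = {}
        for group, cats in self.counts.items():
            total = sum(cats.values())
            out[group] = {c: (v / total if total else float("nan")) for c, v in cats.items()}
        return out

    def same_or_better(self, group: Literal["following", "not_following"]) -> float:
        f = self.frequencies[group]
        return f["better"] + f["equal"]

    @property
    def total(self) -> int:
        return sum(v for cats in self.counts.values() for v in cats.values()) + self.unscored

    def to_frame(self) -> pd.DataFrame:
        rows = []
        freqs = self.frequencies
        for group in ("following", "not_following"):
            for cat in TRANSITION_CATEGORIES:
                rows.append(
                    {
                        "policy_followed": group == "following",
                        "category": cat,
                        "count": self.counts[group][cat],
                        "frequency": freqs[group][cat],
                    }
                )
        return pd.DataFrame(rows)


def loocv_generality(
    dataset: LongitudinalDataset,
    assignment: StateAssignment,
    perturbation: str | Sequence[str],
    schema: PerturbationSchema | None = None,
    reward_schema: Literal["best", "not_worst"] = "best",
    utility: UtilityVector | None = None,
    discount: float = 0.9,
    epsilon: float = 1e-6,
    unobserved_policy: Literal["self_loop", "uniform"] = "self_loop",
    action_timing: Literal["interval_start", "subject_constant"] = "interval_start",
) -> GeneralityReport:
    """Leave-one-subject-out evaluation of policy generality.

    For each subject i, a policy πᵢ* is trained on all other subjects'
    triples. Each of subject i's transitions (s, a, s′) lands in bucket
    ``following`` if a = πᵢ*(s), else ``not_following``, crossed with the
    better/equal/worse classification of s → s′ under the utility.
    Transitions out of states the training fold never visited go to a
    separate ``unscored`` tally (their πᵢ*(s) is fallback, not evidence).
    """
    from .mdp_core import build_reward  # local: avoids a cycle at import time

    if utility is None:
        raise ValueError("loocv_generality needs a utility vector")
    triples = extract_triples(
        dataset, assignment, perturbation, schema=schema, action_timing=action_timing
    )
    df = triples.triples
    subjects = [s for s in dataset.subjects if (df["subject_id"] == s).any()]
    if len(subjects) < 2:
        raise ValueError("LOOCV needs at least 2 subjects with transitions")
    if schema is None and isinstance(perturbation, str):
        from .mdp_core import schema_from_column

        schema = schema_from_column(dataset.metadata[perturbation], perturbation)
    states = assignment.states
    actions = schema.levels
    reward = build_reward(utility, reward_schema, states=states)

    counts = {g: {c: 0 for c in TRANSITION_CATEGORIES} for g in ("following", "not_following")}
    unscored = 0
    per_subject_rows = []
    for held_out in subjects:
        train = df[df["subject_id"] != held_out]
        if train.empty:
            raise ValueError(f"training fold for subject {held_out!r} is empty")
        train_counts = count_triples(_triples_view(train), states, actions)
        model = build_mdp(train_counts, reward, discount, unobserved_policy)
        policy = value_iteration(model, epsilon)
        seen_states = {
            states[i]
            for i in range(len(states))
            if train_counts.counts[i].sum() > 0
        }
        for row in df[df["subject_id"] == held_out].itertuples(index=False):
            if row.from_state not in seen_states:
                unscored += 1
                continue
            group = "following" if row.action == policy[row.from_state] else "not_following"
            category = classify_transition(row.from_state, row.to_state, utility)
            counts[group][category] += 1
            per_subject_rows.append(
                {"subject_id": held_out, "group": group, "category": category}
            )
    per_subject = (
        pd.DataFrame(per_subject_rows, columns=["subject_id", "group", "category"])
        if per_subject_rows
        else None
    )
    return GeneralityReport(counts=counts, unscored=unscored, per_subject=per_subject)


def _triples_view(df: pd.DataFrame):
    """Wrap a triples DataFrame slice for count_triples."""
    from .mdp_core import TripleList

    return TripleList(df.reset_index(drop=True))
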