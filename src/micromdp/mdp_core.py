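"""The microbiome MDP ⟨S, A, T, R⟩ and its value-iteration solution.

The controllable dimension is a *perturbation* — an external intervention on
the interval between two consecutive samples of a subject. Each perturbation
defines a finite action set A (binary, nominal, or a discretisation of a
continuous dose); one MDP is built per perturbation, and a few perturbations
can be merged via the cartesian product of their action sets.

Each subject's time series is split into triples (s, a, s′): the microbiome
was in state s and reached s′ under action a. Transition probabilities are
the multinomial maximum-likelihood estimates

    P(s′ | s, a) = counts(s, a, s′) / Σ_k counts(s, a, k).

Rewards depend on states only, via a utility vector U(S):

    R_best(s)      = 1  iff s = argmax U(S)          (pursue the best state)
    R_not_worst(s) = 1  iff s ≠ argmin U(S)          (avoid the worst state)

The optimal policy π* maximises expected discounted reward and is found by
value iteration with span-seminorm stopping; ties in the greedy step break
to the lowest action index so reruns are reproducible.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_preprocess import LongitudinalDataset
from .state_space import StateAssignment, UtilityVector

logger = logging.getLogger("micromdp")

#: Warn when a combined action set grows beyond this size.
COMBINED_ACTIONS_WARN = 16

#: Action label used when joining member actions of a combined perturbation.
COMBINE_JOINER = ""


# ---------------------------------------------------------------------------
# Actions
# ---------------------------------------------------------------------------

@dataclass
class PerturbationSchema:
    """How a raw metadata column maps to a finite action set A.

    ``kind="binary"``/``"nominal"``: ``levels`` lists the allowed labels and
    raw values must match one of them (after str-strip). ``kind="discretized"``:
    ``bin_edges`` are ascending interior edges splitting the real line into
    ``len(levels)`` left-closed, right-open bins ([low, high)), the last bin
    closed on the right at +inf.
    """

    name: str
    kind: Literal["binary", "nominal", "discretized"]
    levels: list[str]
    bin_edges: list[float] | None = None

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise ValueError(f"perturbation {self.name!r}: need at least 2 action levels")
        if len(set(self.levels)) != len(self.levels):
            raise ValueError(f"perturbation {self.name!r}: duplicate levels")
        if self.kind == "binary" and len(self.levels) != 2:
            raise ValueError(f"binary perturbation {self.name!r} must have exactly 2 levels")
        if self.kind == "discretized":
            if self.bin_edges is None or len(self.bin_edges) != len(self.levels) - 1:
                raise ValueError(
                    f"discretized perturbation {self.name!r}: need len(levels)-1 bin edges"
                )
            if list(self.bin_edges) != sorted(self.bin_edges):
                raise ValueError(f"bin edges must be ascending: {self.bin_edges}")


def discretize_perturbation(raw_values: Sequence, schema: PerturbationSchema) -> list[str]:
    """Map raw per-interval values to action labels.

    Binary/nominal values must equal one of the schema levels. Continuous
    values fall into left-closed, right-open bins: with levels
    ``[low, med, high]`` and edges ``[10, 50]``, value 10 is ``med``.
    """
    out: list[str] = []
    if schema.kind in ("binary", "nominal"):
        allowed = set(schema.levels)
        for v in raw_values:
            label = str(v).strip()
            if label not in allowed:
                raise ValueError(
                    f"perturbation {schema.name!r}: value {v!r} is not one of {schema.levels}"
                )
            out.append(label)
        return out
    edges = np.asarray(schema.bin_edges, dtype=float)
    for v in raw_values:
        x = float(v)
        idx = int(np.searchsorted(edges, x, side="right"))  # [low, high) bins
        out.append(schema.levels[idx])
    return out


def combine_actions(schemas: Sequence[PerturbationSchema], joiner: str = COMBINE_JOINER) -> PerturbationSchema:
    """Cartesian-product action set over several perturbations.

    Single-schema input passes through unchanged. Combined labels are the
    member labels concatenated in schema order (e.g. binary {s, c} × {p, c}
    gives {sp, sc, cp, cc}). Emits a warning when |A| exceeds
    ``COMBINED_ACTIONS_WARN`` — with many perturbations the product explodes
    (8 binary schemas already give 2^8 = 256 actions) and the transition
    table becomes too sparse to estimate.
    """
    schemas = list(schemas)
    if not schemas:
        raise ValueError("no schemas to combine")
    if len(schemas) == 1:
        return schemas[0]
    levels = [joiner.join(combo) for combo in itertools.product(*(s.levels for s in schemas))]
    if len(levels) != len(set(levels)):
        raise ValueError("combined labels collide; use a non-empty joiner")
    if len(levels) > COMBINED_ACTIONS_WARN:
        logger.warning(
            "combined action set has %d actions; the transition table will be sparse",
            len(levels),
        )
    name = "+".join(s.name for s in schemas)
    return PerturbationSchema(name=name, kind="nominal", levels=levels)


# ---------------------------------------------------------------------------
# Triples and transition estimation
# ---------------------------------------------------------------------------

@dataclass
class TripleList:
    """Observed (subject, s, a, s′) transitions, one per consecutive interval."""

    triples: pd.DataFrame  # columns: subject_id, from_state, action, to_state, from_time, to_time
    skipped: int = 0  # intervals dropped for missing perturbation metadata

    def __len__(self) -> int:
        return len(self.triples)


def extract_triples(
    dataset: LongitudinalDataset,
    assignment: StateAssignment,
    perturbation: str | Sequence[str],
    schema: PerturbationSchema | None = None,
    action_timing: Literal["interval_start", "subject_constant"] = "interval_start",
    max_gap: float | None = None,
    member_schemas: Sequence[PerturbationSchema] | None = None,
) -> TripleList:
    """Split each subject's series into (s, a, s′) triples.

    A subject with samples at times t₁ < … < t_m yields m − 1 triples. The
    action on interval (tᵢ, tᵢ₊₁) is the perturbation value recorded on the
    earlier sample (``interval_start``), or the subject's constant value
    (``subject_constant``, for interventions applied once at the outset whose
    effect persists, e.g. a vaccine given before day 0). Intervals with a
    missing perturbation value are skipped and counted. ``max_gap`` drops
    intervals longer than the given time difference (default: no limit,
    every consecutive pair is a transition regardless of gap).

    For combined perturbations pass a list of names plus the combined
    schema from :func:`combine_actions`; the interval action is the tuple of
    member actions, concatenated.
    """
    names = [perturbation] if isinstance(perturbation, str) else list(perturbation)
    for nm in names:
        if nm not in dataset.metadata.columns:
            raise ValueError(f"metadata has no perturbation column {nm!r}")
    if schema is None:
        if len(names) > 1:
            raise ValueError("combined perturbations need an explicit combined schema")
        schema = schema_from_column(dataset.metadata[names[0]], names[0])

    if len(names) > 1 and member_schemas is None:
        member_schemas = [schema_from_column(dataset.metadata[nm], nm) for nm in names]
    elif len(names) == 1:
        member_schemas = None

    rows = []
    skipped = 0
    for subject in dataset.subjects:
        samples = dataset.subject_samples(subject)
        if len(samples) < 2:
            continue
        sids = samples["sample_id"].tolist()
        times = samples["time_point"].tolist()
        for i in range(len(samples) - 1):
            src = samples.iloc[0] if action_timing == "subject_constant" else samples.iloc[i]
            raw = [src[nm] for nm in names]
            if any(pd.isna(v) for v in raw):
                skipped += 1
                continue
            if max_gap is not None and (times[i + 1] - times[i]) > max_gap:
                skipped += 1
                continue
            if member_schemas is not None:
                parts = [discretize_perturbation([v], ms)[0] for v, ms in zip(raw, member_schemas)]
                action = COMBINE_JOINER.join(parts)
                if action not in schema.levels:
                    raise ValueError(f"combined action {action!r} not in schema levels")
            else:
                action = discretize_perturbation([raw[0]], schema)[0]
            rows.append(
                {
                    "subject_id": subject,
                    "from_state": assignment.state_of(sids[i]),
                    "action": action,
                    "to_state": assignment.state_of(sids[i + 1]),
                    "from_time": times[i],
                    "to_time": times[i + 1],
                }
            )
    if skipped:
        logger.info("extract_triples(%s): skipped %d intervals with missing metadata", names, skipped)
    cols = ["subject_id", "from_state", "action", "to_state", "from_time", "to_time"]
    return TripleList(pd.DataFrame(rows, columns=cols), skipped=skipped)


def schema_from_column(column: pd.Series, name: str) -> PerturbationSchema:
    """Infer a binary/nominal schema from the distinct values of a column."""
    values = sorted({str(v).strip() for v in column.dropna()})
    if len(values) < 2:
        raise ValueError(f"perturbation column {name!r} has fewer than 2 distinct values")
    kind = "binary" if len(values) == 2 else "nominal"
    return PerturbationSchema(name=name, kind=kind, levels=values)


@dataclass
class TransitionCounts:
    """counts(s, a, s′) as a dense |S| × |A| × |S| integer array."""

    states: list[str]
    actions: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        expected = (len(self.states), len(self.actions), len(self.states))
        self.counts = np.asarray(self.counts)
        if self.counts.shape != expected:
            raise ValueError(f"counts shape {self.counts.shape} != {expected}")
        if (self.counts < 0).any():
            raise ValueError("negative transition counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def scaled(self, m: float) -> "TransitionCounts":
        return TransitionCounts(self.states, self.actions, self.counts * m)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"state": s, "action": a, "next_state": s2, "count": int(self.counts[i, j, k])}
            for i, s in enumerate(self.states)
            for j, a in enumerate(self.actions)
            for k, s2 in enumerate(self.states)
        ]
        return pd.DataFrame(rows)


def count_triples(
    triples: TripleList, states: Sequence[str], actions: Sequence[str]
) -> TransitionCounts:
    """Tally the triple list into a counts(s, a, s′) array."""
    states = list(states)
    actions = list(actions)
    s_idx = {s: i for i, s in enumerate(states)}
    a_idx = {a: j for j, a in enumerate(actions)}
    counts = np.zeros((len(states), len(actions), len(states)), dtype=np.int64)
    for row in triples.triples.itertuples(index=False):
        counts[s_idx[row.from_state], a_idx[row.action], s_idx[row.to_state]] += 1
    return TransitionCounts(states, actions, counts)


@dataclass
class TransitionTable:
    """Estimated T: probs[s, a] is a probability vector over next states."""

    states: list[str]
    actions: list[str]
    probs: np.ndarray
    observed_mask: np.ndarray  # (|S|, |A|) bool: row backed by >=1 observed triple

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        expected = (len(self.states), len(self.actions), len(self.states))
        if self.probs.shape != expected:
            raise ValueError(f"probs shape {self.probs.shape} != {expected}")
        if (self.probs < 0).any():
            raise ValueError("negative transition probabilities")
        sums = self.probs.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "state": s, "action": a, "next_state": s2,
                "prob": float(self.probs[i, j, k]),
                "observed": bool(self.observed_mask[i, j]),
            }
            for i, s in enumerate(self.states)
            for j, a in enumerate(self.actions)
            for k, s2 in enumerate(self.states)
        ]
        return pd.DataFrame(rows)


def estimate_transition_table(
    counts: TransitionCounts,
    unobserved_policy: Literal["self_loop", "uniform"] = "self_loop",
) -> TransitionTable:
    """Multinomial MLE: each observed (s, a) row is counts / row-sum.

    (s, a) pairs never observed (row sum 0) carry no information; they are
    filled per ``unobserved_policy`` — ``self_loop`` presumes the unknown
    action keeps the state (conservative), ``uniform`` spreads mass evenly —
    and flagged False in ``observed_mask`` so downstream evaluation can
    down-weight them.
    """
    c = counts.counts.astype(float)
    row_sums = c.sum(axis=2)
    observed = row_sums > 0
    n_s, n_a = observed.shape
    probs = np.zeros_like(c)
    safe = np.where(row_sums == 0, 1.0, row_sums)
    probs = c / safe[:, :, None]
    for i in range(n_s):
        for j in range(n_a):
            if not observed[i, j]:
                if unobserved_policy == "self_loop":
                    probs[i, j, i] = 1.0
                else:
                    probs[i, j, :] = 1.0 / n_s
    return TransitionTable(counts.states, counts.actions, probs, observed)


# ---------------------------------------------------------------------------
# Rewards
# ---------------------------------------------------------------------------

@dataclass
class RewardVector:
    """0/1 state reward under one of the two goal schemas."""

    states: list[str]
    values: np.ndarray
    schema: Literal["best", "not_worst"]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.states),):
            raise ValueError("reward length must match the state set")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.states, self.values.tolist()))


def build_reward(
    utility: UtilityVector,
    schema: Literal["best", "not_worst"],
    states: Sequence[str] | None = None,
) -> RewardVector:
    """R_best: indicator of argmax U. R_not_worst: 1 everywhere but argmin U.

    Errors on a tied extremum — with a tie the goal (or anti-goal) state is
    undefined and an external utility must break it.
    """
    states = list(states) if states is not None else list(utility.values)
    missing = [s for s in states if s not in utility.values]
    if missing:
        raise ValueError(f"utility missing states: {missing}")
    if schema == "best":
        goal = utility.argmax()
        values = np.array([1.0 if s == goal else 0.0 for s in states])
    elif schema == "not_worst":
        worst = utility.argmin()
        values = np.array([0.0 if s == worst else 1.0 for s in states])
    else:
        raise ValueError(f"unknown reward schema {schema!r}")
    return RewardVector(states, values, schema)


# ---------------------------------------------------------------------------
# The model and its solution
# ---------------------------------------------------------------------------

@dataclass
class MDPModel:
    """⟨S, A, T, R⟩ with a discount factor γ ∈ (0, 1)."""

    states: list[str]
    actions: list[str]
    transition: TransitionTable
    reward: RewardVector
    discount: float = 0.9

    def __post_init__(self) -> None:
        if not (0.0 < self.discount < 1.0):
            raise ValueError(f"discount must lie in (0, 1), got {self.discount}")
        if self.transition.states != self.states or self.transition.actions != self.actions:
            raise ValueError("transition table dimensions disagree with the model")
        if self.reward.states != self.states:
            raise ValueError("reward dimensions disagree with the model")


@dataclass
class Policy:
    """A deterministic state → action map with its value function."""

    states: list[str]
    actions: list[str]
    mapping: dict[str, str]
    values: dict[str, float]
    n_iterations: int = 0

    def action_indices(self) -> np.ndarray:
        a_idx = {a: j for j, a in enumerate(self.actions)}
        return np.array([a_idx[self.mapping[s]] for s in self.states])

    def __getitem__(self, state: str) -> str:
        return self.mapping[state]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "state": self.states,
                "action": [self.mapping[s] for s in self.states],
                "value": [self.values[s] for s in self.states],
            }
        )


def value_iteration(model: MDPModel, epsilon: float = 1e-6, max_iter: int = 100_000) -> Policy:
    """Solve the MDP by value iteration with span-seminorm stopping.

    Bellman backups V ← max_a [R + γ T_a V] run until
    span(V_{n+1} − V_n) < ε(1 − γ)/γ, which bounds the loss of the greedy
    policy by ε. Greedy ties break to the lowest action index (np.argmax),
    so the result is deterministic.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    T = model.transition.probs  # (S, A, S)
    R = model.reward.values  # (S,)
    gamma = model.discount
    n_s = len(model.states)
    V = np.zeros(n_s)
    threshold = epsilon * (1.0 - gamma) / gamma
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        Q = R[:, None] + gamma * np.einsum("ijk,k->ij", T, V)
        V_new = Q.max(axis=1)
        diff = V_new - V
        span = diff.max() - diff.min()
        V = V_new
        if span < threshold:
            break
    # span stopping leaves V short of V* by ~ a constant; the midpoint
    # correction c·γ/(1−γ) (Puterman §6.6) recovers V* to within ε
    c = 0.5 * (diff.max() + diff.min())
    V = V + c * gamma / (1.0 - gamma)
    greedy = np.argmax(Q, axis=1)
    mapping = {s: model.actions[greedy[i]] for i, s in enumerate(model.states)}
    values = {s: float(V[i]) for i, s in enumerate(model.states)}
    return Policy(model.states, model.actions, mapping, values, n_iterations=n_iter)


def policy_value(model: MDPModel, action_indices: np.ndarray) -> np.ndarray:
    """Exact value of a fixed deterministic policy: solve (I − γ T_π) V = R."""
    n_s = len(model.states)
    T_pi = model.transition.probs[np.arange(n_s), action_indices, :]
    A = np.eye(n_s) - model.discount * T_pi
    return np.linalg.solve(A, model.reward.values)


def build_mdp(
    counts: TransitionCounts,
    reward: RewardVector,
    discount: float = 0.9,
    unobserved_policy: Literal["self_loop", "uniform"] = "self_loop",
) -> MDPModel:
    """Convenience: estimate T from counts and assemble the model."""
    table = estimate_transition_table(counts, unobserved_policy=unobserved_policy)
    return MDPModel(counts.states, counts.actions, table, reward, discount)
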