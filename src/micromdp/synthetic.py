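"""Synthetic longitudinal cohorts with a known ground-truth MDP.

Each cohort is generated from an explicit ⟨S, A, T⟩: per subject, an initial
state is drawn, then at every step an action (random per interval, or held
constant per subject as for a one-off intervention like a vaccine) and the
next state from the true transition row. A sample's taxon counts are drawn
Dirichlet-multinomially around its state's composition profile — the
concentration parameter is the single knob tying state separability to
clustering difficulty (large = crisp community state types, small =
overlapping compositions).

Ground-truth state sequences are returned out of band so tests can score
recovery without leaking truth into the pipeline inputs. The default cohort
shape (24 subjects × 6 time points, two-level treatment held constant per
subject) mirrors a small animal-study design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_preprocess import AbundanceMatrix, LongitudinalDataset, write_abundance_table
from .mdp_core import (
    MDPModel,
    PerturbationSchema,
    RewardVector,
    TransitionTable,
    build_mdp,
    count_triples,
    extract_triples,
    value_iteration,
)
from .state_space import (
    StateAssignment,
    cluster_states,
    compute_state_utility,
    shannon_alpha_diversity,
    UtilityVector,
)


@dataclass
class GeneratorSpec:
    """Full description of a synthetic cohort.

    ``true_transition``: array (|S|, |A|, |S|), rows summing to 1.
    ``state_profiles``: array (|S|, n_taxa) of taxon proportions per state.
    ``profile_concentration``: Dirichlet sharpness of per-sample composition
    around the state profile (200 by default: clearly separated states with
    realistic overdispersion).
    """

    n_states: int
    action_labels: list[str]
    true_transition: np.ndarray
    state_profiles: np.ndarray
    profile_concentration: float = 200.0
    read_depth: int = 20_000
    n_subjects: int = 24
    timepoints_per_subject: int | list[int] = 6
    action_assignment: str = "per_subject_constant"  # or per_interval_random
    perturbation_name: str = "treatment"
    initial_state_probs: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.true_transition = np.asarray(self.true_transition, dtype=float)
        self.state_profiles = np.asarray(self.state_profiles, dtype=float)
        n_s, n_a = self.n_states, len(self.action_labels)
        if self.true_transition.shape != (n_s, n_a, n_s):
            raise ValueError(
                f"true_transition shape {self.true_transition.shape} != {(n_s, n_a, n_s)}"
            )
        if not np.allclose(self.true_transition.sum(axis=2), 1.0, atol=1e-9):
            raise ValueError("true_transition rows must sum to 1")
        if self.state_profiles.shape[0] != n_s:
            raise ValueError("need one composition profile per state")
        if not np.allclose(self.state_profiles.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("state_profiles rows must sum to 1")
        if self.profile_concentration <= 0:
            raise ValueError("profile_concentration must be positive")
        if self.action_assignment not in ("per_subject_constant", "per_interval_random"):
            raise ValueError(f"unknown action_assignment {self.action_assignment!r}")

    @property
    def n_taxa(self) -> int:
        return self.state_profiles.shape[1]

    @property
    def state_names(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.n_states)]

    def timepoints(self, subject_index: int) -> int:
        if isinstance(self.timepoints_per_subject, int):
            return self.timepoints_per_subject
        return self.timepoints_per_subject[subject_index]

    def true_table(self) -> TransitionTable:
        mask = np.ones((self.n_states, len(self.action_labels)), dtype=bool)
        return TransitionTable(self.state_names, list(self.action_labels), self.true_transition, mask)

    def true_utility(self) -> UtilityVector:
        """Shannon diversity of each state's composition profile."""
        values = {
            s: shannon_alpha_diversity(self.state_profiles[i])
            for i, s in enumerate(self.state_names)
        }
        return UtilityVector(values=values, source="alpha_diversity")


def generate_cohort(spec: GeneratorSpec) -> tuple[LongitudinalDataset, dict[str, list[str]]]:
    """Simulate a cohort from the spec's ground-truth MDP.

    Returns the assembled dataset (abundances + metadata + schema, shaped
    exactly like the output of the IO layer) and the true per-subject state
    sequences keyed by subject id.
    """
    rng = np.random.default_rng(spec.seed)
    n_s, n_a = spec.n_states, len(spec.action_labels)
    init = (
        np.full(n_s, 1.0 / n_s)
        if spec.initial_state_probs is None
        else np.asarray(spec.initial_state_probs, dtype=float)
    )
    meta_rows = []
    abundance_rows = []
    sample_ids = []
    truth: dict[str, list[str]] = {}
    for si in range(spec.n_subjects):
        subject = f"subj{si + 1:03d}"
        m = spec.timepoints(si)
        state = int(rng.choice(n_s, p=init))
        states = [state]
        constant_action = int(rng.integers(n_a))
        actions = []
        for t in range(m - 1):
            a = constant_action if spec.action_assignment == "per_subject_constant" else int(rng.integers(n_a))
            actions.append(a)
            state = int(rng.choice(n_s, p=spec.true_transition[state, a]))
            states.append(state)
        truth[subject] = [spec.state_names[s] for s in states]
        for t in range(m):
            sid = f"{subject}_t{t}"
            sample_ids.append(sid)
            # action recorded on the sample starting each interval; the last
            # sample repeats the subject-constant action (no interval follows)
            if spec.action_assignment == "per_subject_constant":
                act = spec.action_labels[constant_action]
            else:
                act = spec.action_labels[actions[t]] if t < m - 1 else None
            composition = rng.dirichlet(spec.profile_concentration * spec.state_profiles[states[t]])
            counts = rng.multinomial(spec.read_depth, composition)
            abundance_rows.append(counts)
            meta_rows.append(
                {
                    "sample_id": sid,
                    "subject_id": subject,
                    "time_point": t,
                    spec.perturbation_name: act,
                    "true_state": spec.state_names[states[t]],
                }
            )
    taxa = [f"taxon{j + 1:03d}" for j in range(spec.n_taxa)]
    matrix = AbundanceMatrix(
        pd.DataFrame(np.array(abundance_rows), index=pd.Index(sample_ids), columns=taxa),
        units_mode="counts",
    )
    metadata = pd.DataFrame(meta_rows)
    schema = PerturbationSchema(
        name=spec.perturbation_name,
        kind="binary" if n_a == 2 else "nominal",
        levels=list(spec.action_labels),
    )
    dataset = LongitudinalDataset(matrix, metadata, [schema])
    return dataset, truth


def true_state_assignment(dataset: LongitudinalDataset) -> StateAssignment:
    """Oracle assignment from the generator's ``true_state`` metadata column."""
    from .state_space import assign_states_external

    return assign_states_external(dataset, "true_state")


def write_cohort(dataset: LongitudinalDataset, outdir: str | Path) -> tuple[Path, Path]:
    """Write the standard abundance + metadata TSV pair for file-based tests."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ab_path = outdir / "abundance.tsv"
    meta_path = outdir / "metadata.tsv"
    write_abundance_table(dataset.abundance, ab_path)
    meta = dataset.metadata.drop(columns=["true_state"], errors="ignore")
    meta.to_csv(meta_path, sep="\t", index=False)
    return ab_path, meta_path


@dataclass
class RecoveryReport:
    """How well the full pipeline recovers the generator's ground truth."""

    state_agreement: float  # fraction of samples whose cluster matches truth
    chosen_k: int
    tv_error: dict[tuple[str, str], float]  # aligned (state, action) -> total variation
    max_tv_error: float
    policy_matches_truth: bool
    solved_policy: dict[str, str]
    true_policy: dict[str, str]


def recovery_suite(
    spec: GeneratorSpec,
    reward_schema: str = "best",
    discount: float = 0.9,
    k_max: int | None = None,
    cluster_seed: int = 0,
) -> RecoveryReport:
    """Run cluster → triples → estimate → solve on a generated cohort.

    Clusters are aligned to true states by majority vote (each cluster maps
    to the true state most frequent among its members). Total-variation
    error is reported per (state, action) row that the cohort observed, and
    the solved policy is compared with the policy solved on the true
    transition table under the true utility.
    """
    dataset, truth = generate_cohort(spec)
    flat_truth = {
        f"{subj}_t{t}": st for subj, seq in truth.items() for t, st in enumerate(seq)
    }
    k_hi = k_max if k_max is not None else min(spec.n_states + 2, dataset.n_samples - 1)
    assignment = cluster_states(
        dataset.abundance, k_min=2, k_max=k_hi, seed=cluster_seed
    )
    # majority-vote alignment cluster -> true state
    votes: dict[str, dict[str, int]] = {}
    for sid, cl in assignment.membership.items():
        votes.setdefault(cl, {})
        votes[cl][flat_truth[sid]] = votes[cl].get(flat_truth[sid], 0) + 1
    alignment = {cl: max(v, key=v.get) for cl, v in votes.items()}
    agree = np.mean(
        [alignment[cl] == flat_truth[sid] for sid, cl in assignment.membership.items()]
    )

    aligned_membership = {sid: alignment[cl] for sid, cl in assignment.membership.items()}
    aligned_states = list(dict.fromkeys(alignment.values()))
    if len(aligned_states) < 2:
        raise ValueError("clustering collapsed onto a single true state; cannot build an MDP")
    aligned = StateAssignment(
        states=aligned_states,
        membership=aligned_membership,
        provenance="clustered",
        clustering_params=assignment.clustering_params,
    )

    schema = dataset.perturbation_schemas[0]
    timing = (
        "subject_constant"
        if spec.action_assignment == "per_subject_constant"
        else "interval_start"
    )
    triples = extract_triples(
        dataset, aligned, spec.perturbation_name, schema=schema, action_timing=timing
    )
    counts = count_triples(triples, aligned.states, schema.levels)
    utility = compute_state_utility(aligned, dataset.abundance, mode="alpha_diversity")
    from .mdp_core import build_reward

    reward = build_reward(utility, reward_schema, states=aligned.states)
    model = build_mdp(counts, reward, discount)
    solved = value_iteration(model)

    true_states = spec.state_names
    true_utility = spec.true_utility()
    true_reward = build_reward(true_utility, reward_schema, states=true_states)
    true_model = MDPModel(
        true_states, list(spec.action_labels), spec.true_table(), true_reward, discount
    )
    true_policy = value_iteration(true_model)

    s_idx = {s: i for i, s in enumerate(true_states)}
    tv: dict[tuple[str, str], float] = {}
    for i, s in enumerate(aligned.states):
        for j, a in enumerate(schema.levels):
            if not model.transition.observed_mask[i, j]:
                continue
            est = model.transition.probs[i, j]
            # re-order the estimated row onto the true state axis
            row = np.zeros(len(true_states))
            for k, s2 in enumerate(aligned.states):
                row[s_idx[s2]] = est[k]
            tru = spec.true_transition[s_idx[s], j]
            tv[(s, a)] = 0.5 * float(np.abs(row - tru).sum())
    policy_match = all(
        solved[s] == true_policy[s] for s in aligned.states
    )
    return RecoveryReport(
        state_agreement=float(agree),
        chosen_k=assignment.clustering_params["k"],
        tv_error=tv,
        max_tv_error=max(tv.values()) if tv else float("nan"),
        policy_matches_truth=policy_match,
        solved_policy=dict(solved.mapping),
        true_policy=dict(true_policy.mapping),
    )
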