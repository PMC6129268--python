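"""MDP state definition and state utilities.

A state is a group of microbiome samples with similar composition — either
community state types supplied by the study authors (an external label
column), or clusters of the OTU vectors. Clustering here is k-medoids (PAM
style) over a compositional distance, with the number of clusters chosen by
mean silhouette width and an optional bootstrap Jaccard stability report;
the stage is pluggable so a more elaborate robust-clustering protocol can
drop in.

The utility vector U(S) orders states by desirability. By default it is the
per-state mean Shannon alpha diversity of member samples; an external
utility (e.g. the inverse mean Nugent score of each vaginal community state
type) can be supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import entropy
from sklearn.metrics import silhouette_score

from .io_preprocess import AbundanceMatrix, LongitudinalDataset


@dataclass
class StateAssignment:
    """A partition of samples into the MDP state set S."""

    states: list[str]
    membership: dict[str, str]  # sample_id -> state label
    provenance: Literal["external", "clustered"]
    clustering_params: dict | None = None
    bootstrap_jaccard: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if len(self.states) < 2:
            raise ValueError(f"need at least 2 states, got {self.states}")
        extra = set(self.membership.values()) - set(self.states)
        if extra:
            raise ValueError(f"membership uses labels not in the state set: {sorted(extra)}")

    def state_of(self, sample_id: str) -> str:
        return self.membership[sample_id]

    def members(self, state: str) -> list[str]:
        return [s for s, st in self.membership.items() if st == state]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": list(self.membership), "state": list(self.membership.values())}
        )


@dataclass
class UtilityVector:
    """Numerical preference U(s) over states; higher is better."""

    values: dict[str, float]
    source: Literal["alpha_diversity", "external"] = "alpha_diversity"

    def __getitem__(self, state: str) -> float:
        return self.values[state]

    def argmax(self) -> str:
        return self._unique_extremum(max)

    def argmin(self) -> str:
        return self._unique_extremum(min)

    def _unique_extremum(self, fn) -> str:
        extreme = fn(self.values.values())
        winners = [s for s, v in self.values.items() if v == extreme]
        if len(winners) != 1:
            raise ValueError(
                f"utility {fn.__name__} is tied between {winners}; "
                "supply an external utility to break the tie"
            )
        return winners[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"state": list(self.values), "utility": list(self.values.values())})


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------

def shannon_alpha_diversity(abundance_row: np.ndarray, base: float | None = None) -> float:
    """Shannon entropy −Σ pᵢ log pᵢ of a renormalised abundance vector.

    Natural log by default (``base=2`` for bits). Zero entries contribute
    zero; the value is invariant to rescaling the whole row.
    """
    row = np.asarray(abundance_row, dtype=float)
    if row.ndim != 1:
        raise ValueError("expected a 1-D abundance vector")
    if (row < 0).any():
        raise ValueError("abundances must be non-negative")
    total = row.sum()
    if total <= 0:
        raise ValueError("all-zero abundance vector has undefined diversity")
    return float(entropy(row / total, base=base))


def simpson_diversity(abundance_row: np.ndarray) -> float:
    """Gini–Simpson index 1 − Σ pᵢ² (alternative alpha-diversity metric)."""
    row = np.asarray(abundance_row, dtype=float)
    total = row.sum()
    if total <= 0:
        raise ValueError("all-zero abundance vector has undefined diversity")
    p = row / total
    return float(1.0 - np.sum(p * p))


# ---------------------------------------------------------------------------
# External state labels
# ---------------------------------------------------------------------------

def assign_states_external(dataset: LongitudinalDataset, label_column: str) -> StateAssignment:
    """Use a metadata column of pre-defined community state types as S.

    Labels are whitespace-trimmed; the state order is first appearance.
    """
    if label_column not in dataset.metadata.columns:
        raise ValueError(f"metadata has no column {label_column!r}")
    col = dataset.metadata[label_column]
    missing = dataset.metadata.loc[col.isna(), "sample_id"].tolist()
    if missing:
        raise ValueError(f"samples without a state label: {missing}")
    labels = col.astype(str).str.strip()
    if (labels == "").any():
        blank = dataset.metadata.loc[labels == "", "sample_id"].tolist()
        raise ValueError(f"samples without a state label: {blank}")
    states = list(dict.fromkeys(labels))
    membership = dict(zip(dataset.metadata["sample_id"], labels))
    return StateAssignment(states=states, membership=membership, provenance="external")


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def _distance_matrix(props: np.ndarray, distance: str) -> np.ndarray:
    if distance == "jensen-shannon":
        d = squareform(pdist(props, metric="jensenshannon"))
        return np.nan_to_num(d, nan=0.0)  # identical rows give 0/0 inside JS
    if distance == "bray-curtis":
        return squareform(pdist(props, metric="braycurtis"))
    if distance == "euclidean":
        return squareform(pdist(props, metric="euclidean"))
    raise ValueError(f"unknown distance {distance!r}")


def _kmedoids(dist: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 100) -> np.ndarray:
    """k-medoids with k-medoids++ seeding and alternating refinement.

    Returns the medoid index of each point's cluster as integer labels.
    """
    n = dist.shape[0]
    # k-medoids++ init: spread starting medoids proportionally to distance
    medoids = [int(rng.integers(n))]
    for _ in range(k - 1):
        d_min = dist[:, medoids].min(axis=1)
        weights = d_min**2
        if weights.sum() == 0:
            remaining = np.setdiff1d(np.arange(n), medoids)
            medoids.append(int(rng.choice(remaining)))
            continue
        medoids.append(int(rng.choice(n, p=weights / weights.sum())))
    medoids = np.array(sorted(set(medoids)))
    while len(medoids) < k:  # degenerate duplicates in init
        extra = np.setdiff1d(np.arange(n), medoids)
        medoids = np.sort(np.append(medoids, extra[0]))
    for _ in range(max_iter):
        labels = np.argmin(dist[:, medoids], axis=1)
        new_medoids = medoids.copy()
        for ci in range(k):
            members = np.flatnonzero(labels == ci)
            if members.size == 0:
                continue
            within = dist[np.ix_(members, members)].sum(axis=1)
            new_medoids[ci] = members[int(np.argmin(within))]
        new_medoids = np.sort(new_medoids)
        if np.array_equal(new_medoids, medoids):
            break
        medoids = new_medoids
    labels = np.argmin(dist[:, medoids], axis=1)
    return labels


def cluster_states(
    matrix: AbundanceMatrix,
    k_min: int = 2,
    k_max: int = 6,
    distance: Literal["jensen-shannon", "bray-curtis", "euclidean"] = "jensen-shannon",
    n_boot: int = 0,
    seed: int = 0,
    n_restarts: int = 5,
) -> StateAssignment:
    """Cluster OTU vectors into community states by k-medoids.

    Rows are converted to proportions, a pairwise distance matrix is built,
    and for each k in [k_min, k_max] the best of ``n_restarts`` seeded PAM
    runs is kept; the k with the highest mean silhouette width wins. With
    ``n_boot > 0`` a cluster-wise bootstrap Jaccard stability is attached.
    Deterministic for a fixed seed. State labels are ``"S1"…"Sk"`` ordered by
    first appearance along the sample axis.
    """
    n = matrix.shape[0]
    if not (2 <= k_min <= k_max):
        raise ValueError("need 2 <= k_min <= k_max")
    if k_max >= n:
        raise ValueError(f"k_max={k_max} must be below the number of samples ({n})")
    props = matrix.data.to_numpy(dtype=float)
    sums = props.sum(axis=1, keepdims=True)
    if (sums == 0).any():
        raise ValueError("all-zero sample rows cannot be clustered")
    props = props / sums
    n_distinct = len(np.unique(props.round(12), axis=0))
    if n_distinct < k_min:
        raise ValueError(f"only {n_distinct} distinct composition(s); k_min={k_min} unattainable")
    dist = _distance_matrix(props, distance)
    rng = np.random.default_rng(seed)

    best = None  # (silhouette, k, labels)
    for k in range(k_min, min(k_max, n_distinct) + 1):
        for _ in range(n_restarts):
            labels = _kmedoids(dist, k, rng)
            if len(np.unique(labels)) < 2:
                continue
            score = silhouette_score(dist, labels, metric="precomputed")
            if best is None or score > best[0]:
                best = (score, k, labels)
    if best is None:
        raise ValueError("clustering failed to produce a valid partition")
    _, k, labels = best

    # relabel clusters in order of first appearance, as stable state names
    order: dict[int, str] = {}
    for lab in labels:
        if lab not in order:
            order[lab] = f"S{len(order) + 1}"
    named = [order[lab] for lab in labels]
    states = [order[lab] for lab in order]
    membership = dict(zip(matrix.sample_ids, named))

    jaccard = None
    if n_boot > 0:
        jaccard = _bootstrap_jaccard(dist, labels, k, n_boot, rng)
        jaccard = {order[ci]: v for ci, v in jaccard.items()}

    return StateAssignment(
        states=states,
        membership=membership,
        provenance="clustered",
        clustering_params={
            "k": k, "distance": distance, "n_boot": n_boot, "seed": seed,
            "silhouette": float(best[0]),
        },
        bootstrap_jaccard=jaccard,
    )


def _bootstrap_jaccard(
    dist: np.ndarray, labels: np.ndarray, k: int, n_boot: int, rng: np.random.Generator
) -> dict[int, float]:
    """Mean best-match Jaccard of each reference cluster over bootstrap reruns."""
    n = dist.shape[0]
    totals = {ci: [] for ci in range(k)}
    for _ in range(n_boot):
        idx = np.unique(rng.integers(0, n, size=n))
        if len(np.unique(labels[idx])) < 2 or len(idx) <= k:
            continue
        sub = dist[np.ix_(idx, idx)]
        boot_labels = _kmedoids(sub, k, rng)
        for ci in range(k):
            ref = set(np.flatnonzero(labels[idx] == ci))
            if not ref:
                continue
            best = 0.0
            for cj in np.unique(boot_labels):
                got = set(np.flatnonzero(boot_labels == cj))
                jac = len(ref & got) / len(ref | got)
                best = max(best, jac)
            totals[ci].append(best)
    return {ci: float(np.mean(v)) if v else float("nan") for ci, v in totals.items()}


# ---------------------------------------------------------------------------
# Utility
# ---------------------------------------------------------------------------

def compute_state_utility(
    assignment: StateAssignment,
    matrix: AbundanceMatrix | None = None,
    mode: Literal["alpha_diversity", "external"] = "alpha_diversity",
    external_values: Mapping[str, float] | None = None,
    diversity_metric: Literal["shannon", "shannon2", "simpson"] = "shannon",
) -> UtilityVector:
    """Build U(S): per-state mean alpha diversity, or supplied values.

    In ``alpha_diversity`` mode each state's utility is the mean diversity of
    its member samples' abundance rows; in ``external`` mode the supplied
    mapping is used verbatim (and must cover every state).
    """
    if mode == "external":
        if external_values is None:
            raise ValueError("external mode needs external_values")
        missing = [s for s in assignment.states if s not in external_values]
        if missing:
            raise ValueError(f"external utility missing states: {missing}")
        return UtilityVector(
            values={s: float(external_values[s]) for s in assignment.states},
            source="external",
        )
    if matrix is None:
        raise ValueError("alpha_diversity mode needs an abundance matrix")
    metric = {
        "shannon": shannon_alpha_diversity,
        "shannon2": lambda r: shannon_alpha_diversity(r, base=2),
        "simpson": simpson_diversity,
    }[diversity_metric]
    values: dict[str, float] = {}
    for state in assignment.states:
        members = assignment.members(state)
        present = [m for m in members if m in set(matrix.sample_ids)]
        if not present:
            raise ValueError(f"state {state!r} has no member samples in the abundance matrix")
        values[state] = float(np.mean([metric(matrix.row(m)) for m in present]))
    return UtilityVector(values=values, source="alpha_diversity")
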