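"""Tabular and diagram exports of solved models and their evaluations.

Everything written here is re-derivable from the serialized transition
counts plus the run configuration — no hidden state. Diagrams are GraphViz
DOT text: one node per state with the goal state highlighted, one edge per
(s, a, s′) above a display threshold, labelled ``action: prob``, with
optimal-policy edges marked in red.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .evaluation import GeneralityReport, StabilityReport
from .mdp_core import MDPModel, Policy, TransitionCounts, TransitionTable


def _quote(s: str) -> str:
    return '"' + str(s).replace('"', r"\"") + '"'


def export_dot(
    model: MDPModel,
    policy: Policy,
    path: str | Path,
    prob_threshold: float = 0.01,
) -> Path:
    """Write the solved MDP as a GraphViz DOT state diagram.

    Edges with probability below ``prob_threshold`` are omitted for
    readability (the full table lives in the TSV export). Edges taken by
    the optimal policy are red and bold; the goal state (reward-1 state
    under the ``best`` schema, any reward-1 state otherwise) is filled red.
    """
    path = Path(path)
    goal_states = {
        s for s, r in zip(model.states, model.reward.values) if r == 1.0
    }
    if model.reward.schema == "not_worst":
        # avoid painting everything: highlight the state to avoid instead
        avoid = {s for s, r in zip(model.states, model.reward.values) if r == 0.0}
        goal_states = set()
    else:
        avoid = set()
    lines = ["digraph mdp {", "  rankdir=LR;", "  node [shape=ellipse];"]
    for s in model.states:
        attrs = []
        if s in goal_states:
            attrs.append('style=filled, fillcolor="#cc3333", fontcolor=white, goal=true')
        if s in avoid:
            attrs.append('style=filled, fillcolor="#555555", fontcolor=white, avoid=true')
        lines.append(f"  {_quote(s)} [{', '.join(attrs)}];" if attrs else f"  {_quote(s)};")
    for i, s in enumerate(model.states):
        for j, a in enumerate(model.actions):
            for k, s2 in enumerate(model.states):
                p = float(model.transition.probs[i, j, k])
                if p <= prob_threshold:
                    continue
                attrs = [f"label={_quote(f'{a}: {p:.2f}')}"]
                if policy[s] == a:
                    attrs.append('color=red, penwidth=2.0, policy=true')
                lines.append(f"  {_quote(s)} -> {_quote(s2)} [{', '.join(attrs)}];")
    lines.append("}")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_counts(counts: TransitionCounts, path: str | Path) -> Path:
    path = Path(path)
    counts.to_frame().to_csv(path, sep="\t", index=False)
    return path


def write_transition_table(table: TransitionTable, path: str | Path) -> Path:
    path = Path(path)
    table.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def write_policy(policy: Policy, path: str | Path) -> Path:
    path = Path(path)
    policy.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def write_stability(report: StabilityReport, path: str | Path) -> Path:
    """Per-state/per-action stability ratios (barplot data)."""
    path = Path(path)
    report.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def write_stability_aggregate(
    aggregates: dict[str, dict[str, float]], path: str | Path
) -> Path:
    """Aggregate stability JSON: perturbation → reward schema → ratio."""
    path = Path(path)
    path.write_text(json.dumps(aggregates, indent=2, sort_keys=True) + "\n")
    return path


def write_generality(report: GeneralityReport, path: str | Path) -> Path:
    """LOOCV frequencies by compliance × category, plus the unscored tally."""
    path = Path(path)
    frame = report.to_frame()
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
    side = path.with_suffix(".json")
    side.write_text(
        json.dumps(
            {
                "counts": report.counts,
                "frequencies": report.frequencies,
                "unscored": report.unscored,
                "same_or_better_following": report.same_or_better("following"),
                "same_or_better_not_following": report.same_or_better("not_following"),
            },
            indent=2,
        )
        + "\n"
    )
    return path
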