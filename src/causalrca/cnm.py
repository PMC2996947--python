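"""Causal Network Model assembly across experiments.

Hypotheses scored independently per experiment are intersected — a mechanism
is retained only when it meets the significance floor, with a consistent
direction, in *every* experiment — then merged into one network whose
explanatory coverage of each experiment's state changes is accounted
explicitly.  This is the step that turns "different genes change in every
model, yet the same upstream mechanisms are at work" into a quantitative
statement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .engine import (
    DEFAULT_DEPTH,
    Hypothesis,
    Polarity,
    Tier,
    _changes_by_node,
    evaluate_all,
)
from .kam import Kam, KamNode, downstream_neighborhood, write_kam
from .quantify import Direction, StateChange

__all__ = [
    "Experiment",
    "CoverageRecord",
    "CausalNetworkModel",
    "build_experiment",
    "common_hypotheses",
    "change_overlap",
    "coverage",
    "assemble_cnm",
    "write_cnm",
]

_TIER_RANK = {Tier.SIGNIFICANT: 0, Tier.MARGINAL: 1, Tier.NOT_SIGNIFICANT: 2}


@dataclass
class Experiment:
    """One comparison (cell line / model / timepoint) with its scored hypotheses."""

    name: str
    universe: frozenset[KamNode]
    changes: dict[KamNode, Direction]
    hypotheses: list[Hypothesis] = field(default_factory=list)

    def hypothesis_for(self, root: KamNode) -> Hypothesis | None:
        for h in self.hypotheses:
            if h.root == root:
                return h
        return None


def build_experiment(
    kam: Kam,
    name: str,
    universe: Iterable[KamNode],
    changes: Iterable[StateChange] | Mapping[KamNode, Direction],
    depth: int = DEFAULT_DEPTH,
    **evaluate_kwargs,
) -> Experiment:
    """Run the full per-experiment evaluation and bundle the result."""
    universe_set = frozenset(universe)
    changed = _changes_by_node(changes)
    hypotheses = evaluate_all(kam, universe_set, changed, depth, **evaluate_kwargs)
    return Experiment(name, universe_set, changed, hypotheses)


@dataclass
class CoverageRecord:
    """Per-experiment accounting of what the selected mechanisms explain."""

    explained: int
    contradicted: int
    conflicted: int
    total_changes: int

    @property
    def fraction(self) -> float:
        return self.explained / self.total_changes if self.total_changes else 0.0


@dataclass
class CausalNetworkModel:
    """Merged subgraph of the selected mechanisms plus coverage accounting."""

    selected_roots: tuple[tuple[KamNode, Direction], ...]
    subgraph: Kam
    per_experiment_coverage: dict[str, CoverageRecord]
    root_annotations: dict[KamNode, dict]


# ---------------------------------------------------------------------------
# Selection and overlap
# ---------------------------------------------------------------------------


def common_hypotheses(
    experiments: Sequence[Experiment],
    tier_floor: Tier | str = Tier.SIGNIFICANT,
    require_same_direction: bool = True,
) -> list[tuple[KamNode, Direction]]:
    """Roots meeting the tier floor in every experiment, deterministically ordered.

    With ``require_same_direction`` the selected direction must be identical
    across experiments; otherwise the first experiment's direction is
    reported.
    """
    if not experiments:
        raise ValueError("need at least one experiment")
    floor = _TIER_RANK[Tier(tier_floor)]
    selected: list[tuple[KamNode, Direction]] = []
    first = experiments[0]
    for h in first.hypotheses:
        if _TIER_RANK[h.tier] > floor:
            continue
        direction = h.direction
        keep = True
        for other in experiments[1:]:
            oh = other.hypothesis_for(h.root)
            if oh is None or _TIER_RANK[oh.tier] > floor:
                keep = False
                break
            if require_same_direction and oh.direction != direction:
                keep = False
                break
        if keep:
            selected.append((h.root, direction))
    selected.sort(key=lambda rd: (rd[0], rd[1].value))
    return selected


def change_overlap(experiments: Sequence[Experiment]) -> pd.DataFrame:
    """Venn-style counts of shared (node, direction) state-change pairs.

    Returns one row per experiment subset of size >= 2 plus the full
    intersection, with the member names and the shared count.  Symmetric
    under experiment reordering.
    """
    if len(experiments) < 2:
        raise ValueError("need at least two experiments for an overlap report")
    sets = {
        e.name: {(node, d) for node, d in e.changes.items()} for e in experiments
    }
    names = sorted(sets)
    rows = []
    for size in range(2, len(names) + 1):
        for combo in combinations(names, size):
            shared = set.intersection(*(sets[n] for n in combo))
            rows.append(
                {
                    "experiments": "&".join(combo),
                    "n_experiments": size,
                    "shared_changes": len(shared),
                }
            )
    return pd.DataFrame(rows, columns=["experiments", "n_experiments", "shared_changes"])


def full_intersection(experiments: Sequence[Experiment]) -> set[tuple[KamNode, Direction]]:
    """The (node, direction) pairs changed identically in every experiment."""
    sets = [{(node, d) for node, d in e.changes.items()} for e in experiments]
    return set.intersection(*sets) if sets else set()


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------


def _selected_predictions(
    kam: Kam,
    selected: Sequence[tuple[KamNode, Direction]],
    depth: int,
) -> dict[KamNode, set[Polarity]]:
    """Union of unambiguous predictions of the selected roots, under their directions."""
    predicted: dict[KamNode, set[Polarity]] = {}
    for root, direction in selected:
        if root not in kam:
            raise KeyError(f"selected root {root.label} not in knowledge graph")
        flip = direction == Direction.DECREASE
        for node, signs in downstream_neighborhood(kam, root, depth).items():
            if len(signs) != 1:
                continue  # ambiguous under this root: no directional claim
            (sign,) = signs
            if flip:
                sign = -sign
            predicted.setdefault(node, set()).add(
                Polarity.INCREASE if sign > 0 else Polarity.DECREASE
            )
    return predicted


def coverage(
    selected: Sequence[tuple[KamNode, Direction]],
    experiments: Sequence[Experiment],
    kam: Kam,
    depth: int = DEFAULT_DEPTH,
) -> dict[str, CoverageRecord]:
    """How many of each experiment's changes the selected mechanisms explain.

    A changed node is *explained* when at least one selected root
    unambiguously predicts its observed direction and none predicts the
    opposite; *contradicted* when only opposite predictions reach it; and
    *conflicted* when selected roots disagree about it.
    """
    predicted = _selected_predictions(kam, selected, depth)
    out: dict[str, CoverageRecord] = {}
    for exp in experiments:
        explained = contradicted = conflicted = 0
        for node, observed in exp.changes.items():
            polarities = predicted.get(node)
            if not polarities:
                continue
            agree = Polarity(observed.value) in polarities
            disagree = len(polarities - {Polarity(observed.value)}) > 0
            if agree and not disagree:
                explained += 1
            elif disagree and not agree:
                contradicted += 1
            else:
                conflicted += 1
        out[exp.name] = CoverageRecord(
            explained, contradicted, conflicted, len(exp.changes)
        )
    return out


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


def _kam_digraph(kam: Kam) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(kam.nodes)
    for e in kam.edges:
        g.add_edge(e.source, e.target)
    return g


def assemble_cnm(
    selected: Sequence[tuple[KamNode, Direction]],
    kam: Kam,
    experiments: Sequence[Experiment],
    depth: int = DEFAULT_DEPTH,
    perturbation: KamNode | None = None,
) -> CausalNetworkModel:
    """Merge the selected mechanisms into one Causal Network Model.

    The subgraph unions (a) every simple causal path of length <= ``depth``
    between selected roots and (b) every simple path of length <= ``depth``
    from a selected root to a state-change node it explains.  Per-root
    annotations record the computable vetting criteria: causally downstream
    of the designated perturbation node, causally connected to another
    selected root, and whether the root's entity is itself an observed state
    change — the judgment calls stay with the scientist.
    """
    digraph = _kam_digraph(kam)
    roots = [r for r, _ in selected]
    for root in roots:
        if root not in kam:
            raise KeyError(f"selected root {root.label} not in knowledge graph")

    keep_edges: set[tuple[KamNode, KamNode]] = set()
    # (a) inter-root causal paths
    for a in roots:
        for b in roots:
            if a == b:
                continue
            for path in nx.all_simple_paths(digraph, a, b, cutoff=depth):
                keep_edges.update(zip(path, path[1:]))
    # (b) root -> explained change paths
    predicted = _selected_predictions(kam, selected, depth)
    explained_nodes = {
        node
        for exp in experiments
        for node, observed in exp.changes.items()
        if predicted.get(node) == {Polarity(observed.value)}
    }
    for root, _ in selected:
        reach = downstream_neighborhood(kam, root, depth)
        for node in explained_nodes:
            if node in reach:
                for path in nx.all_simple_paths(digraph, root, node, cutoff=depth):
                    keep_edges.update(zip(path, path[1:]))

    sub = Kam(name=f"{kam.name}_cnm")
    for e in kam.edges:
        if (e.source, e.target) in keep_edges:
            sub.add_edge(e)
    for root in roots:  # roots always present even if isolated
        sub.add_node(root)

    changed_entities = {
        node.entity_id for exp in experiments for node in exp.changes
    }
    annotations: dict[KamNode, dict] = {}
    inter_root = {
        r
        for r in roots
        if any(
            other != r
            and (
                next(nx.all_simple_paths(digraph, r, other, cutoff=depth), None)
                or next(nx.all_simple_paths(digraph, other, r, cutoff=depth), None)
            )
            for other in roots
        )
    }
    for root, direction in selected:
        annotations[root] = {
            "direction": direction.value,
            "downstream_of_perturbation": bool(
                perturbation is not None
                and perturbation in kam
                and nx.has_path(digraph, perturbation, root)
            ),
            "connected_to_other_roots": root in inter_root and len(roots) > 1,
            "root_is_state_change": root.entity_id in changed_entities,
        }

    return CausalNetworkModel(
        tuple(selected),
        sub,
        coverage(selected, experiments, kam, depth),
        annotations,
    )


def write_cnm(cnm: CausalNetworkModel, subgraph_path, annotation_path) -> None:
    """Export the merged subgraph (kamtsv) and a JSON annotation sidecar."""
    write_kam(cnm.subgraph, subgraph_path)
    payload = {
        "selected_roots": [
            {"entity": r.entity_id, "aspect": r.aspect.value, "direction": d.value}
            for r, d in cnm.selected_roots
        ],
        "root_annotations": {
            r.label: ann for r, ann in sorted(cnm.root_annotations.items())
        },
        "per_experiment_coverage": {
            name: {
                "explained": rec.explained,
                "contradicted": rec.contradicted,
                "conflicted": rec.conflicted,
                "total_changes": rec.total_changes,
                "fraction": rec.fraction,
            }
            for name, rec in sorted(cnm.per_experiment_coverage.items())
        },
    }
    with open(annotation_path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
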