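"""Reverse causal analysis: score every graph node as an upstream hypothesis.

A hypothesis is a knowledge-graph node assumed to be *increased*.  Searching a
bounded number of causal steps downstream yields predictions — measured nodes
with a polarity of increase, decrease or ambiguous (the latter when paths with
contradictory sign products reach the node).  Two figures of merit compare
predictions with the observed state changes:

Richness
    Hypergeometric upper-tail p-value for over-representation of observed
    changes among the predicted nodes: with N measured nodes, M observed
    changes, P predictions and Q nodes both predicted and changed, it is
    Pr[X >= Q] for X hypergeometric(N, M, P).  Direction-blind, so ambiguous
    predictions count.

Concordance
    Binomial upper-tail p-value for directional agreement: with K changes
    supporting an increased root and J supporting a decreased root
    (ambiguous predictions contribute to neither), it is Pr[X >= H] for
    X ~ Binomial(J + K, 0.5), H = max(J, K).  The root's reported direction
    is whichever explains more changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .kam import Kam, KamNode, downstream_neighborhood
from .quantify import Direction, StateChange

__all__ = [
    "Polarity",
    "Tier",
    "Prediction",
    "Hypothesis",
    "richness_p",
    "concordance_p",
    "select_direction",
    "classify_tier",
    "compose_hypothesis",
    "evaluate_all",
    "hypothesis_table",
    "prediction_detail",
]

DEFAULT_DEPTH = 2
SIGNIFICANT_CUTOFF = 0.05
MARGINAL_CUTOFF = 0.1


class Polarity(str, Enum):
    INCREASE = "increase"
    DECREASE = "decrease"
    AMBIGUOUS = "ambiguous"


class Tier(str, Enum):
    SIGNIFICANT = "significant"
    MARGINAL = "marginal"
    NOT_SIGNIFICANT = "not_significant"


_TIER_ORDER = {Tier.SIGNIFICANT: 0, Tier.MARGINAL: 1, Tier.NOT_SIGNIFICANT: 2}

_POLARITY_FROM_SIGNS = {
    frozenset({+1}): Polarity.INCREASE,
    frozenset({-1}): Polarity.DECREASE,
    frozenset({+1, -1}): Polarity.AMBIGUOUS,
}


@dataclass(frozen=True)
class Prediction:
    """A downstream node with its polarity under an increased root."""

    node: KamNode
    polarity: Polarity


@dataclass
class Hypothesis:
    """One scored root with its prediction set and counts.

    Counts: N measured nodes, M observed changes, P predictions over measured
    nodes, Q predicted-and-changed, K/J changes supporting an
    increased/decreased root.  ``direction`` reports the better-supported
    root direction (``tie`` marks J == K, resolved to increase).
    """

    root: KamNode
    direction: Direction
    tie: bool
    predictions: tuple[Prediction, ...]
    N: int
    M: int
    P: int
    Q: int
    J: int
    K: int
    richness_p: float
    concordance_p: float
    tier: Tier

    @property
    def H(self) -> int:
        return max(self.J, self.K)

    def sort_key(self):
        return (
            _TIER_ORDER[self.tier],
            self.concordance_p,
            self.richness_p,
            -self.Q,
            self.root,
        )


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


def richness_p(Q: int, N: int, M: int, P: int) -> float:
    """Hypergeometric upper tail Pr[X >= Q]; population N, successes M, draws P."""
    if not (0 <= M <= N and 0 <= P <= N):
        raise ValueError(f"need 0 <= M, P <= N; got N={N}, M={M}, P={P}")
    if not 0 <= Q <= min(M, P):
        raise ValueError(f"need 0 <= Q <= min(M, P); got Q={Q}, M={M}, P={P}")
    if Q == 0:
        return 1.0
    return float(stats.hypergeom.sf(Q - 1, N, M, P))


def concordance_p(J: int, K: int) -> float:
    """Binomial upper tail Pr[X >= max(J, K)] with n = J + K and p = 0.5."""
    if J < 0 or K < 0:
        raise ValueError("J and K must be non-negative")
    n = J + K
    if n == 0:
        return 1.0
    return float(stats.binom.sf(max(J, K) - 1, n, 0.5))


def select_direction(J: int, K: int) -> tuple[Direction, bool]:
    """Root direction explaining more changes; ties resolve to increase, flagged."""
    if K > J:
        return Direction.INCREASE, False
    if J > K:
        return Direction.DECREASE, False
    return Direction.INCREASE, True


def classify_tier(
    richness: float,
    concordance: float,
    significant_cutoff: float = SIGNIFICANT_CUTOFF,
    marginal_cutoff: float = MARGINAL_CUTOFF,
) -> Tier:
    """Both p-values must meet a cutoff jointly: 0.05 significant, 0.1 marginal."""
    if richness <= significant_cutoff and concordance <= significant_cutoff:
        return Tier.SIGNIFICANT
    if richness <= marginal_cutoff and concordance <= marginal_cutoff:
        return Tier.MARGINAL
    return Tier.NOT_SIGNIFICANT


# ---------------------------------------------------------------------------
# Hypothesis composition
# ---------------------------------------------------------------------------


def _changes_by_node(
    changes: Iterable[StateChange] | Mapping[KamNode, Direction],
) -> dict[KamNode, Direction]:
    """Normalise a state-change collection to node -> changed direction."""
    if isinstance(changes, Mapping):
        return {
            n: Direction(d)
            for n, d in changes.items()
            if Direction(d) != Direction.NO_CHANGE
        }
    return {sc.node: sc.direction for sc in changes if sc.changed}


def compose_hypothesis(
    kam: Kam,
    root: KamNode,
    universe: Iterable[KamNode],
    changes: Iterable[StateChange] | Mapping[KamNode, Direction],
    depth: int = DEFAULT_DEPTH,
    significant_cutoff: float = SIGNIFICANT_CUTOFF,
    marginal_cutoff: float = MARGINAL_CUTOFF,
) -> Hypothesis:
    """Compose and score one root against the measured universe.

    Predictions are the measured nodes reachable from ``root`` within
    ``depth`` causal steps, with polarity from the attainable path-sign
    products.  Ambiguously predicted changed nodes count toward Q (richness
    is direction-blind) but never toward J or K.
    """
    universe_set = frozenset(universe)
    if not universe_set:
        raise ValueError("measured universe is empty")
    if root not in kam:
        raise KeyError(f"root {root.label} not in knowledge graph")
    changed = _changes_by_node(changes)
    stray = set(changed) - universe_set
    if stray:
        raise ValueError(
            f"changed nodes outside the measured universe: "
            f"{sorted(n.label for n in stray)[:5]}"
        )

    neighborhood = downstream_neighborhood(kam, root, depth)
    predictions = tuple(
        Prediction(node, _POLARITY_FROM_SIGNS[signs])
        for node, signs in sorted(neighborhood.items())
        if node in universe_set
    )

    N = len(universe_set)
    M = len(changed)
    P = len(predictions)
    Q = J = K = 0
    for pred in predictions:
        observed = changed.get(pred.node)
        if observed is None:
            continue
        Q += 1
        if pred.polarity == Polarity.AMBIGUOUS:
            continue
        if pred.polarity.value == observed.value:
            K += 1
        else:
            J += 1

    rich = richness_p(Q, N, M, P)
    conc = concordance_p(J, K)
    direction, tie = select_direction(J, K)
    tier = classify_tier(rich, conc, significant_cutoff, marginal_cutoff)
    return Hypothesis(
        root, direction, tie, predictions, N, M, P, Q, J, K, rich, conc, tier
    )


def evaluate_all(
    kam: Kam,
    universe: Iterable[KamNode],
    changes: Iterable[StateChange] | Mapping[KamNode, Direction],
    depth: int = DEFAULT_DEPTH,
    significant_cutoff: float = SIGNIFICANT_CUTOFF,
    marginal_cutoff: float = MARGINAL_CUTOFF,
    adjust_across_hypotheses: bool = False,
) -> list[Hypothesis]:
    """Score every graph node with at least one measured prediction.

    Returns hypotheses ranked by (tier, concordance, richness, Q descending,
    root id) — a deterministic ordering.  With ``adjust_across_hypotheses``
    both p-value families are BH-adjusted across the evaluated roots before
    tier classification (off by default; the raw-cutoff regime is the
    standard one).
    """
    universe_set = frozenset(universe)
    changed = _changes_by_node(changes)
    adjacency = kam.adjacency()
    hypotheses = []
    # nodes without outgoing edges predict nothing and are skipped outright
    for root in sorted(adjacency):
        hyp = compose_hypothesis(
            kam, root, universe_set, changed, depth,
            significant_cutoff, marginal_cutoff,
        )
        if hyp.P >= 1:
            hypotheses.append(hyp)
    if adjust_across_hypotheses and hypotheses:
        from .quantify import bh_adjust

        rich = bh_adjust([h.richness_p for h in hypotheses])
        conc = bh_adjust([h.concordance_p for h in hypotheses])
        for h, r, c in zip(hypotheses, rich, conc):
            h.richness_p = float(r)
            h.concordance_p = float(c)
            h.tier = classify_tier(r, c, significant_cutoff, marginal_cutoff)
    hypotheses.sort(key=Hypothesis.sort_key)
    return hypotheses


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def hypothesis_table(hypotheses: Iterable[Hypothesis]) -> pd.DataFrame:
    """Ranked hypothesis report with counts, p-values and tier."""
    return pd.DataFrame(
        [
            {
                "root_entity": h.root.entity_id,
                "root_aspect": h.root.aspect.value,
                "direction": h.direction.value,
                "tie": h.tie,
                "N": h.N,
                "M": h.M,
                "P": h.P,
                "Q": h.Q,
                "J": h.J,
                "K": h.K,
                "richness_p": h.richness_p,
                "concordance_p": h.concordance_p,
                "tier": h.tier.value,
            }
            for h in hypotheses
        ],
        columns=[
            "root_entity", "root_aspect", "direction", "tie",
            "N", "M", "P", "Q", "J", "K",
            "richness_p", "concordance_p", "tier",
        ],
    )


def prediction_detail(
    hypothesis: Hypothesis,
    changes: Iterable[StateChange] | Mapping[KamNode, Direction],
) -> pd.DataFrame:
    """Per-prediction table; rows inconsistent with the root are flagged ``X``.

    Polarities are shown under the hypothesis's *selected* direction (the
    composed increase-rooted polarities are mirrored when the selected
    direction is decrease).
    """
    changed = _changes_by_node(changes)
    flip = hypothesis.direction == Direction.DECREASE
    rows = []
    for pred in hypothesis.predictions:
        polarity = pred.polarity
        if flip and polarity != Polarity.AMBIGUOUS:
            polarity = (
                Polarity.DECREASE
                if polarity == Polarity.INCREASE
                else Polarity.INCREASE
            )
        observed = changed.get(pred.node)
        if observed is None or polarity == Polarity.AMBIGUOUS:
            consistent = ""
        elif polarity.value == observed.value:
            consistent = ""
        else:
            consistent = "X"
        rows.append(
            {
                "node": pred.node.label,
                "polarity": polarity.value,
                "observed": observed.value if observed else "no_change",
                "consistent": consistent,
            }
        )
    return pd.DataFrame(rows, columns=["node", "polarity", "observed", "consistent"])
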