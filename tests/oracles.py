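"""Independent brute-force oracles used to check the package's statistics.

Everything here is deliberately naive — exact integer arithmetic and
exhaustive enumeration — and shares no code path with the implementation
under test.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

from causalrca.kam import Kam


def hypergeom_upper_tail(Q: int, N: int, M: int, P: int) -> float:
    """Pr[X >= Q] for X ~ Hypergeometric(N, M, P), by exact summation."""
    lo = max(0, M + P - N)
    hi = min(M, P)
    if Q <= lo:
        return 1.0
    total = sum(comb(M, x) * comb(N - M, P - x) for x in range(Q, hi + 1))
    return float(Fraction(total, comb(N, P)))


def binom_upper_tail(H: int, n: int) -> float:
    """Pr[X >= H] for X ~ Binomial(n, 1/2), by exact summation."""
    if H <= 0:
        return 1.0
    total = sum(comb(n, x) for x in range(H, n + 1))
    return float(Fraction(total, 2**n))


def bh_step_up(p_values) -> list[float]:
    """Textbook Benjamini-Hochberg step-up: min over k >= rank of p(k)*n/k."""
    n = len(p_values)
    order = sorted(range(n), key=lambda i: p_values[i])
    adjusted = [0.0] * n
    running_min = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p_values[i] * n / rank_from_top)
        adjusted[i] = running_min
    return adjusted


def enumerate_simple_paths(
    edges: list[tuple[str, str, int]], root: str, depth: int
) -> dict[str, set[int]]:
    """All sign products over directed simple paths of length <= depth.

    Works on plain (source, target, sign) triples so it stays independent of
    the graph data model.
    """
    reached: dict[str, set[int]] = {}

    def extend(path_nodes: list[str], product: int) -> None:
        if len(path_nodes) - 1 >= depth:
            return
        for src, tgt, sign in edges:
            if src != path_nodes[-1] or tgt in path_nodes:
                continue
            reached.setdefault(tgt, set()).add(product * sign)
            extend(path_nodes + [tgt], product * sign)

    extend([root], +1)
    return reached


def kam_edge_triples(kam: Kam) -> list[tuple[str, str, int]]:
    return [(e.source.label, e.target.label, e.sign) for e in kam.edges]


def count_hypothesis(
    edges: list[tuple[str, str, int]],
    root: str,
    depth: int,
    universe: set[str],
    changes: dict[str, int],
) -> dict[str, int]:
    """Exhaustive N/M/P/Q/J/K counts; changes map label -> +1/-1."""
    reached = enumerate_simple_paths(edges, root, depth)
    predictions = {n: s for n, s in reached.items() if n in universe}
    N = len(universe)
    M = sum(1 for n in changes if n in universe)
    P = len(predictions)
    Q = J = K = 0
    for node, signs in predictions.items():
        observed = changes.get(node)
        if observed is None:
            continue
        Q += 1
        if len(signs) == 2:
            continue
        (sign,) = signs
        if sign == observed:
            K += 1
        else:
            J += 1
    return {"N": N, "M": M, "P": P, "Q": Q, "J": J, "K": K}
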