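import numpy as np
import pytest

from causalrca.kam import CausalEdge, Kam, KamNode


def node(label: str) -> KamNode:
    return KamNode.from_label(label)


def make_kam(*triples: tuple[str, str, int], name: str = "toy") -> Kam:
    """Build a graph from (source_label, target_label, sign) triples."""
    kam = Kam(name=name)
    for src, tgt, sign in triples:
        kam.add_edge(CausalEdge(node(src), node(tgt), sign))
    return kam


def random_kam(
    rng: np.random.Generator, n_nodes: int = 10, edge_prob: float = 0.25
) -> Kam:
    """Random signed digraph (possibly cyclic, possibly contradictory edges)."""
    labels = [f"N{i}.act" for i in range(n_nodes)]
    kam = Kam(name="random")
    for lbl in labels:
        kam.add_node(node(lbl))
    for i in range(n_nodes):
        for j in range(n_nodes):
            if i == j:
                continue
            if rng.random() < edge_prob:
                sign = -1 if rng.random() < 0.4 else +1
                kam.add_edge(CausalEdge(node(labels[i]), node(labels[j]), sign))
                if rng.random() < 0.1:  # contradictory twin
                    kam.add_edge(
                        CausalEdge(node(labels[i]), node(labels[j]), -sign)
                    )
    return kam


@pytest.fixture
def chain_kam() -> Kam:
    """A --(+)--> B --(-)--> C."""
    return make_kam(("A.act", "B.act", +1), ("B.act", "C.rna", -1))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
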