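"""Signed causal knowledge graph: node/edge model, I/O, and polarity search.

The knowledge substrate for reverse causal analysis is a directed graph whose
nodes are (entity, aspect) pairs — e.g. the kinase activity of AKT1 versus the
RNA abundance of CCNG2 — and whose edges are literature-curated cause→effect
assertions carrying a sign: noninverting (+1, "increases") or inverting
(-1, "decreases").  Contradictory assertions (both signs between the same pair
of nodes) are legitimate content, not errors; they are what makes downstream
polarity "ambiguous".
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Iterator, Mapping

__all__ = [
    "Aspect",
    "Species",
    "KamNode",
    "CausalEdge",
    "Kam",
    "KamFormatError",
    "load_kam",
    "write_kam",
    "downstream_neighborhood",
]


class Aspect(str, Enum):
    """What facet of a biological entity a node represents."""

    RNA_ABUNDANCE = "rna_abundance"
    PROTEIN_ABUNDANCE = "protein_abundance"
    PROTEIN_ACTIVITY = "protein_activity"
    PROTEIN_MODIFICATION = "protein_modification"
    COMPOUND = "compound"
    PROCESS = "process"


#: Short aliases accepted in dotted node labels (``AKT1.act``) alongside the
#: full enum tokens.
ASPECT_ALIASES: Mapping[str, Aspect] = {
    "rna": Aspect.RNA_ABUNDANCE,
    "prot": Aspect.PROTEIN_ABUNDANCE,
    "act": Aspect.PROTEIN_ACTIVITY,
    "mod": Aspect.PROTEIN_MODIFICATION,
    "pmod": Aspect.PROTEIN_MODIFICATION,
    "cmpd": Aspect.COMPOUND,
    **{a.value: a for a in Aspect},
}


class Species(str, Enum):
    """Origin of a causal assertion (orthologous assertions carry rat/mouse)."""

    HUMAN = "human"
    RAT = "rat"
    MOUSE = "mouse"


def parse_aspect(token: str) -> Aspect:
    try:
        return ASPECT_ALIASES[token.strip().lower()]
    except KeyError:
        raise KamFormatError(f"unknown aspect token {token!r}") from None


@dataclass(frozen=True, order=True)
class KamNode:
    """A graph node: one aspect of one biological entity."""

    entity_id: str
    aspect: Aspect

    def __post_init__(self) -> None:
        if not self.entity_id:
            raise ValueError("entity_id must be non-empty")
        if not isinstance(self.aspect, Aspect):
            object.__setattr__(self, "aspect", Aspect(self.aspect))

    @property
    def label(self) -> str:
        """Dotted ``ENTITY.aspect`` label used by the sif dialect."""
        return f"{self.entity_id}.{self.aspect.value}"

    @classmethod
    def from_label(cls, label: str) -> "KamNode":
        if "." not in label:
            raise KamFormatError(
                f"node label {label!r} lacks a '.aspect' suffix"
            )
        entity, aspect_token = label.rsplit(".", 1)
        return cls(entity, parse_aspect(aspect_token))

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.label


@dataclass(frozen=True)
class CausalEdge:
    """A signed cause→effect assertion with its supporting citations."""

    source: KamNode
    target: KamNode
    sign: int
    evidence: tuple[str, ...] = ()
    species: Species = Species.HUMAN

    def __post_init__(self) -> None:
        if self.sign not in (+1, -1):
            raise ValueError(f"edge sign must be +1 or -1, got {self.sign!r}")
        if self.source == self.target:
            raise ValueError(f"self-loop on {self.source.label} is not allowed")
        if not isinstance(self.species, Species):
            object.__setattr__(self, "species", Species(self.species))
        object.__setattr__(self, "evidence", tuple(self.evidence))

    @property
    def key(self) -> tuple[KamNode, KamNode, int]:
        return (self.source, self.target, self.sign)


class KamFormatError(ValueError):
    """Raised for malformed knowledge-graph files or tokens."""


class Kam:
    """A signed causal graph.

    Nodes are unique ``(entity, aspect)`` pairs; edges are unique
    ``(source, target, sign)`` triples (duplicates merge their evidence).
    Self-loops are rejected.  Equality compares node sets, edge keys and the
    merged evidence — row order never matters.
    """

    def __init__(
        self,
        nodes: Iterable[KamNode] = (),
        edges: Iterable[CausalEdge] = (),
        name: str = "kam",
    ) -> None:
        self.name = name
        self._nodes: set[KamNode] = set()
        self._edges: dict[tuple[KamNode, KamNode, int], CausalEdge] = {}
        self._adj: dict[KamNode, list[tuple[KamNode, int]]] | None = None
        for n in nodes:
            self.add_node(n)
        for e in edges:
            self.add_edge(e)

    # -- construction -----------------------------------------------------
    def add_node(self, node: KamNode) -> KamNode:
        self._nodes.add(node)
        self._adj = None
        return node

    def add_edge(self, edge: CausalEdge) -> CausalEdge:
        """Insert an edge, merging evidence with any identical triple."""
        existing = self._edges.get(edge.key)
        if existing is not None:
            merged = existing.evidence + tuple(
                ev for ev in edge.evidence if ev not in existing.evidence
            )
            edge = CausalEdge(
                edge.source, edge.target, edge.sign, merged, existing.species
            )
        self._edges[edge.key] = edge
        self._nodes.add(edge.source)
        self._nodes.add(edge.target)
        self._adj = None
        return edge

    # -- views ------------------------------------------------------------
    @property
    def nodes(self) -> frozenset[KamNode]:
        return frozenset(self._nodes)

    @property
    def edges(self) -> tuple[CausalEdge, ...]:
        return tuple(self._edges.values())

    def __len__(self) -> int:
        return len(self._nodes)

    def __contains__(self, node: KamNode) -> bool:
        return node in self._nodes

    def __iter__(self) -> Iterator[KamNode]:
        return iter(self._nodes)

    def adjacency(self) -> Mapping[KamNode, list[tuple[KamNode, int]]]:
        """Outgoing ``node -> [(target, sign), ...]`` map (cached)."""
        if self._adj is None:
            adj: dict[KamNode, list[tuple[KamNode, int]]] = {}
            for e in self._edges.values():
                adj.setdefault(e.source, []).append((e.target, e.sign))
            # deterministic traversal order
            for out in adj.values():
                out.sort(key=lambda ts: (ts[0], ts[1]))
            self._adj = adj
        return self._adj

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Kam):
            return NotImplemented
        return self._nodes == other._nodes and {
            k: e.evidence for k, e in self._edges.items()
        } == {k: e.evidence for k, e in other._edges.items()}

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"Kam({self.name!r}, {len(self._nodes)} nodes, "
            f"{len(self._edges)} edges)"
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

KAMTSV_HEADER = [
    "source_entity",
    "source_aspect",
    "sign",
    "target_entity",
    "target_aspect",
    "species",
    "evidence",
]

_SIGN_TOKENS = {"+": +1, "-": -1}
_SIF_RELATIONS = {"activates": +1, "inhibits": -1}


def load_kam(path, dialect: str = "kamtsv", name: str | None = None) -> Kam:
    """Read a signed causal graph from ``path``.

    Two dialects are supported: ``kamtsv`` (seven tab-separated columns with
    explicit aspects, species and ;-joined evidence) and ``sif_signed``
    (three columns ``source  activates|inhibits  target`` with dotted
    ``ENTITY.aspect`` node labels).  Loading is order-independent: permuting
    the rows of a file yields an identical graph.
    """
    kam = Kam(name=name or str(path))
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        if dialect == "kamtsv":
            _load_kamtsv(reader, kam)
        elif dialect == "sif_signed":
            _load_sif(reader, kam)
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
    return kam


def _load_kamtsv(reader, kam: Kam) -> None:
    header = next(reader, None)
    if header is None or [h.strip() for h in header] != KAMTSV_HEADER:
        raise KamFormatError(
            f"line 1: expected header {' '.join(KAMTSV_HEADER)!r}"
        )
    for lineno, row in enumerate(reader, start=2):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) != 7:
            raise KamFormatError(
                f"line {lineno}: expected 7 tab-separated fields, got {len(row)}"
            )
        se, sa, sign_tok, te, ta, species_tok, evidence = row
        if sign_tok not in _SIGN_TOKENS:
            raise KamFormatError(
                f"line {lineno}: unknown sign token {sign_tok!r}"
            )
        try:
            src = KamNode(se, parse_aspect(sa))
            tgt = KamNode(te, parse_aspect(ta))
            species = Species(species_tok.strip().lower())
        except (KamFormatError, ValueError) as exc:
            raise KamFormatError(f"line {lineno}: {exc}") from None
        ev = tuple(tok for tok in evidence.split(";") if tok)
        try:
            kam.add_edge(
                CausalEdge(src, tgt, _SIGN_TOKENS[sign_tok], ev, species)
            )
        except ValueError as exc:  # self-loop
            raise KamFormatError(f"line {lineno}: {exc}") from None


def _load_sif(reader, kam: Kam) -> None:
    for lineno, row in enumerate(reader, start=1):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) != 3:
            raise KamFormatError(
                f"line {lineno}: expected 3 tab-separated fields, got {len(row)}"
            )
        src_lbl, rel, tgt_lbl = (tok.strip() for tok in row)
        if rel not in _SIF_RELATIONS:
            raise KamFormatError(
                f"line {lineno}: unknown relation token {rel!r}"
            )
        try:
            src = KamNode.from_label(src_lbl)
            tgt = KamNode.from_label(tgt_lbl)
            kam.add_edge(CausalEdge(src, tgt, _SIF_RELATIONS[rel]))
        except (KamFormatError, ValueError) as exc:
            raise KamFormatError(f"line {lineno}: {exc}") from None


def write_kam(kam: Kam, path, dialect: str = "kamtsv") -> None:
    """Write ``kam`` so that ``load_kam`` round-trips to an equal graph.

    Isolated nodes survive a kamtsv round trip via sentinel-free edge rows
    only when they have edges; nodes without any edge are re-created as
    degenerate rows are not emitted — callers who need isolated nodes should
    keep them in memory.  Rows are emitted in sorted order for diff-ability.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        if dialect == "kamtsv":
            writer.writerow(KAMTSV_HEADER)
            rows = sorted(
                kam.edges,
                key=lambda e: (e.source, e.target, -e.sign),
            )
            for e in rows:
                writer.writerow(
                    [
                        e.source.entity_id,
                        e.source.aspect.value,
                        "+" if e.sign > 0 else "-",
                        e.target.entity_id,
                        e.target.aspect.value,
                        e.species.value,
                        ";".join(e.evidence),
                    ]
                )
        elif dialect == "sif_signed":
            for e in sorted(kam.edges, key=lambda e: (e.source, e.target, -e.sign)):
                rel = "activates" if e.sign > 0 else "inhibits"
                writer.writerow([e.source.label, rel, e.target.label])
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Polarity search
# ---------------------------------------------------------------------------


def downstream_neighborhood(
    kam: Kam, root: KamNode, depth: int = 2
) -> dict[KamNode, frozenset[int]]:
    """Nodes reachable from ``root`` with their attainable path-sign products.

    Enumerates every directed *simple* path (no repeated node) of length at
    most ``depth`` out of ``root`` and records, per reached node, the set of
    products of edge signs along those paths: ``{+1}``, ``{-1}`` or
    ``{+1, -1}`` (the latter is what downstream code treats as ambiguous
    polarity).  The root itself is excluded.  Simple paths keep the search
    finite on cyclic graphs.
    """
    if root not in kam:
        raise KeyError(f"root {root.label} not in graph")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    adj = kam.adjacency()
    result: dict[KamNode, set[int]] = {}
    on_path: set[KamNode] = {root}

    def walk(node: KamNode, sign: int, remaining: int) -> None:
        for target, edge_sign in adj.get(node, ()):
            if target in on_path:
                continue
            product = sign * edge_sign
            result.setdefault(target, set()).add(product)
            if remaining > 1:
                on_path.add(target)
                walk(target, product, remaining - 1)
                on_path.discard(target)

    walk(root, +1, depth)
    return {n: frozenset(s) for n, s in result.items()}
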