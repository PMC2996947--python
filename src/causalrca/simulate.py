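"""Synthetic signed causal graphs and planted-perturbation benchmark data.

Real knowledge assembly models are proprietary and the matching omics data
unreleased, so everything here is generated: a layered signed DAG of
regulator activities feeding RNA-abundance leaves, a planted perturbed root,
replicate lognormal-noise expression matrices with the root's downstream
fold changes baked in, phosphosubstrate ratio tables, and a multi-experiment
fixture with a shared mechanism core for cross-experiment assembly tests.
Every generator draws from one explicitly seeded ``numpy`` generator — same
config, same data.

Topology: ``n_entities`` regulator activity nodes are split into an upstream
layer (wired to downstream regulators) and a downstream layer (wired to RNA
leaves), so a planted upstream root reaches its transcripts in two causal
steps, mimicking activity→activity→expression chains.  Edge signs are
inverting with probability ``inverting_fraction``; with probability
``contradiction_rate`` an edge gains an opposite-sign twin, which is what
makes downstream polarity ambiguous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .kam import Aspect, CausalEdge, Kam, KamNode
from .quantify import Direction, ExpressionExperiment, PhosphoRatioTable

__all__ = [
    "SimConfig",
    "GroundTruth",
    "generate_kam",
    "simulate_expression",
    "simulate_phospho",
    "MultiExperimentFixture",
    "make_multi_experiment_fixture",
]

_DIR_SIGN = {Direction.INCREASE: +1, Direction.DECREASE: -1}
_SIGN_DIR = {+1: Direction.INCREASE, -1: Direction.DECREASE}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the planted-perturbation benchmark.

    Defaults emulate the statistical regime of a replicate microarray
    comparison: log2-scale noise sd 0.25 (tight RMA-style replicates),
    planted linear fold change 2.0, four replicates per group, and a sparse
    layered regulator graph.
    """

    n_entities: int = 200
    n_rna_leaves: int = 120
    upstream_fraction: float = 0.25
    upstream_out_degree: int = 3
    leaf_out_degree: int = 8
    inverting_fraction: float = 0.3
    contradiction_rate: float = 0.02
    planted_roots: tuple[tuple[str, str], ...] = ()
    effect_fold: float = 2.0
    noise_sd: float = 0.25
    n_replicates: int = 4
    background_change_rate: float = 0.01
    n_phospho_substrates: int = 5
    baseline_range: tuple[float, float] = (6.0, 10.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("upstream_fraction", "inverting_fraction",
                     "contradiction_rate", "background_change_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.effect_fold < 1:
            raise ValueError("effect_fold must be >= 1 (1.0 means no effect)")
        if self.leaf_out_degree > self.n_rna_leaves:
            raise ValueError("leaf_out_degree exceeds the number of leaves")


@dataclass
class GroundTruth:
    """What the generator planted, in the engine's own vocabulary.

    ``expected_direction`` maps each unambiguously reachable leaf to the
    direction implied by the planted root directions composed with path-sign
    products; ``conflicted_leaves`` are reachable with both polarities and
    get no planted shift.
    """

    kam: Kam
    planted_roots: tuple[tuple[KamNode, Direction], ...]
    expected_direction: dict[KamNode, Direction]
    conflicted_leaves: set[KamNode]


def _upstream_name(i: int) -> str:
    return f"U{i:03d}"


def _regulator_name(i: int) -> str:
    return f"R{i:03d}"


def _gene_name(i: int) -> str:
    return f"G{i:04d}"


def generate_kam(config: SimConfig) -> tuple[Kam, GroundTruth]:
    """Build a layered signed DAG plus its planted-perturbation ground truth.

    Ground-truth polarities are computed by a forward relaxation over the
    construction layers — independent of the engine's path search, so the
    two can be cross-checked against each other.
    """
    rng = np.random.default_rng(config.seed)
    n_upstream = max(1, round(config.n_entities * config.upstream_fraction))
    n_regulators = config.n_entities - n_upstream
    if n_regulators < 1:
        raise ValueError("config leaves no downstream regulators")
    if config.upstream_out_degree > n_regulators:
        raise ValueError("upstream_out_degree exceeds downstream layer size")

    upstream = [
        KamNode(_upstream_name(i), Aspect.PROTEIN_ACTIVITY)
        for i in range(n_upstream)
    ]
    regulators = [
        KamNode(_regulator_name(i), Aspect.PROTEIN_ACTIVITY)
        for i in range(n_regulators)
    ]
    leaves = [
        KamNode(_gene_name(i), Aspect.RNA_ABUNDANCE)
        for i in range(config.n_rna_leaves)
    ]

    kam = Kam(name=f"synthetic_seed{config.seed}")
    for node in upstream + regulators + leaves:
        kam.add_node(node)

    def draw_sign() -> int:
        return -1 if rng.random() < config.inverting_fraction else +1

    def add(src: KamNode, tgt: KamNode) -> None:
        s = draw_sign()
        kam.add_edge(CausalEdge(src, tgt, s))
        if rng.random() < config.contradiction_rate:
            # opposite-sign twin: deliberate ambiguity
            kam.add_edge(CausalEdge(src, tgt, -s))

    for u in upstream:
        for j in rng.choice(n_regulators, config.upstream_out_degree, replace=False):
            add(u, regulators[j])
    for r in regulators:
        for j in rng.choice(config.n_rna_leaves, config.leaf_out_degree, replace=False):
            add(r, leaves[j])

    planted: list[tuple[KamNode, Direction]] = []
    for entity, direction in config.planted_roots:
        node = next((n for n in upstream + regulators if n.entity_id == entity), None)
        if node is None:
            raise ValueError(f"planted root {entity!r} is not a generated regulator")
        planted.append((node, Direction(direction)))

    # phosphosubstrate children hang off the planted roots (kinase ->
    # substrate phosphorylation, noninverting); with nothing planted the
    # first upstream kinase still gets substrates so ratio tables exist
    substrate_parents = [r for r, _ in planted] or upstream[:1]
    for root in substrate_parents:
        for i in range(config.n_phospho_substrates):
            sub = KamNode(f"{root.entity_id}S{i}", Aspect.PROTEIN_MODIFICATION)
            kam.add_node(sub)
            kam.add_edge(CausalEdge(root, sub, +1))

    ground_truth = GroundTruth(
        kam, tuple(planted), *_propagate_expected(kam, planted, leaves)
    )
    return kam, ground_truth


def _propagate_expected(
    kam: Kam,
    planted: Sequence[tuple[KamNode, Direction]],
    leaves: Sequence[KamNode],
) -> tuple[dict[KamNode, Direction], set[KamNode]]:
    """Layer-order sign relaxation over the DAG (generator-side oracle)."""
    polarity: dict[KamNode, set[int]] = {}
    planted_set = {r for r, _ in planted}
    for root, direction in planted:
        polarity.setdefault(root, set()).add(_DIR_SIGN[direction])
    # two relaxation sweeps suffice: edges only go upstream->regulator->leaf;
    # planted roots keep their clamped direction
    for _ in range(2):
        for edge in kam.edges:
            if edge.target in planted_set:
                continue
            for s in list(polarity.get(edge.source, ())):
                polarity.setdefault(edge.target, set()).add(s * edge.sign)
    leaf_set = set(leaves)
    expected: dict[KamNode, Direction] = {}
    conflicted: set[KamNode] = set()
    for node, signs in polarity.items():
        if node not in leaf_set:
            continue
        if len(signs) == 1:
            expected[node] = _SIGN_DIR[next(iter(signs))]
        else:
            conflicted.add(node)
    return expected, conflicted


def simulate_expression(
    kam: Kam,
    ground_truth: GroundTruth,
    config: SimConfig,
    name: str = "synthetic",
) -> ExpressionExperiment:
    """Replicate log2 expression matrix with the planted shifts baked in.

    Controls are baseline + N(0, noise_sd); treated replicates of leaves
    downstream of the planted roots shift by ±log2(effect_fold) per the
    expected direction.  Conflicted leaves stay flat; each off-target leaf
    flips a ``background_change_rate`` coin for a random-direction shift.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    leaves = sorted(
        (n for n in kam.nodes if n.aspect == Aspect.RNA_ABUNDANCE),
    )
    genes = [n.entity_id for n in leaves]
    n_genes = len(genes)
    lo, hi = config.baseline_range
    baseline = rng.uniform(lo, hi, n_genes)

    shift = np.zeros(n_genes)
    for i, node in enumerate(leaves):
        expected = ground_truth.expected_direction.get(node)
        if expected is not None:
            shift[i] = _DIR_SIGN[expected] * math.log2(config.effect_fold)
        elif node not in ground_truth.conflicted_leaves:
            if rng.random() < config.background_change_rate:
                shift[i] = rng.choice([-1.0, 1.0]) * math.log2(config.effect_fold)

    n = config.n_replicates
    control = baseline[:, None] + rng.normal(0, config.noise_sd, (n_genes, n))
    treated = (
        baseline[:, None]
        + shift[:, None]
        + rng.normal(0, config.noise_sd, (n_genes, n))
    )
    columns = [f"C{i + 1}" for i in range(n)] + [f"T{i + 1}" for i in range(n)]
    matrix = pd.DataFrame(
        np.hstack([control, treated]), index=pd.Index(genes, name="gene"),
        columns=columns,
    )
    design = pd.Series(
        ["control"] * n + ["treated"] * n, index=columns, name="group"
    )
    return ExpressionExperiment(matrix, design, name)


def simulate_phospho(
    ground_truth: GroundTruth,
    config: SimConfig,
    timepoints: Sequence[str] = ("10min", "30min", "2h", "24h"),
) -> PhosphoRatioTable:
    """Treated/vehicle ratio table for the planted roots' phosphosubstrates.

    Substrates of an inhibited (decrease-planted) kinase draw ratios well
    below the 0.80 decrease threshold; substrates of an activated root draw
    above the 1.50 increase threshold; everything else hovers near 1.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    planted = {root: direction for root, direction in ground_truth.planted_roots}
    rows = []
    substrates = sorted(
        n for n in ground_truth.kam.nodes
        if n.aspect == Aspect.PROTEIN_MODIFICATION
    )
    parents = {
        n: [e.source for e in ground_truth.kam.edges if e.target == n]
        for n in substrates
    }
    for node in substrates:
        direction = next(
            (planted[p] for p in parents[node] if p in planted), None
        )
        for tp in timepoints:
            if direction == Direction.DECREASE:
                ratio = rng.uniform(0.40, 0.70)
            elif direction == Direction.INCREASE:
                ratio = rng.uniform(1.60, 2.20)
            else:
                ratio = rng.uniform(0.90, 1.10)
            rows.append(
                {
                    "entity": node.entity_id,
                    "modification": "phospho",
                    "timepoint": tp,
                    "ratio": round(float(ratio), 4),
                }
            )
    return PhosphoRatioTable(
        pd.DataFrame(rows, columns=["entity", "modification", "timepoint", "ratio"])
    )


# ---------------------------------------------------------------------------
# Multi-experiment fixture (shared mechanisms, private responses)
# ---------------------------------------------------------------------------


@dataclass
class MultiExperimentFixture:
    """Shared graph, per-experiment inputs, and the planted cross-experiment truth."""

    kam: Kam
    experiments: list[tuple[str, frozenset[KamNode], dict[KamNode, Direction]]]
    common_roots: tuple[tuple[KamNode, Direction], ...]
    private_roots: dict[str, tuple[KamNode, ...]]
    shared_core: set[tuple[KamNode, Direction]]
    expected_coverage_fraction: float


def make_multi_experiment_fixture(
    n_experiments: int = 3,
    shared_mechanism_size: int = 4,
    private_mechanism_size: int = 2,
    shared_change_core: int = 17,
    config: SimConfig | None = None,
    extra_common_per_experiment: int = 11,
    private_block: int = 10,
    n_background: int = 36,
    n_universe: int = 1000,
) -> MultiExperimentFixture:
    """Experiments that share mechanisms while sharing almost no genes.

    Every experiment's changes are driven one-third by the shared mechanism
    roots — including an exactly shared core of ``shared_change_core``
    (node, direction) pairs — and two-thirds by experiment-private roots and
    background, drawn from per-experiment-disjoint leaf pools.  The measured
    universe (``n_universe`` leaves) is identical across experiments.
    """
    config = config or SimConfig()
    if n_experiments < 1 or shared_mechanism_size < 1:
        raise ValueError("need >= 1 experiment and >= 1 shared mechanism")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))

    n_common_driven = shared_change_core + extra_common_per_experiment
    n_private_total = private_mechanism_size * private_block
    per_exp_total = n_common_driven + n_private_total + n_background
    filler_per_root = 3
    n_leaves_needed = (
        shared_change_core
        + n_experiments * extra_common_per_experiment
        + shared_mechanism_size * filler_per_root
        + n_experiments * n_private_total
        + n_experiments * n_background
    )
    if n_universe < n_leaves_needed:
        raise ValueError(
            f"n_universe={n_universe} cannot hold {n_leaves_needed} structured leaves"
        )

    kam = Kam(name=f"multiexp_seed{config.seed}")
    leaves = [KamNode(_gene_name(i), Aspect.RNA_ABUNDANCE) for i in range(n_universe)]
    for n in leaves:
        kam.add_node(n)
    pool = iter(leaves)

    def take(k: int) -> list[KamNode]:
        return [next(pool) for _ in range(k)]

    def sign() -> int:
        return -1 if rng.random() < config.inverting_fraction else +1

    common_roots: list[tuple[KamNode, Direction]] = []
    for i in range(shared_mechanism_size):
        root = KamNode(f"CM{i:02d}", Aspect.PROTEIN_ACTIVITY)
        kam.add_node(root)
        direction = Direction.INCREASE if i % 2 == 0 else Direction.DECREASE
        common_roots.append((root, direction))

    def wire(root: KamNode, direction: Direction, leaf: KamNode) -> Direction:
        """Edge root->leaf with a random sign; returns the implied leaf direction."""
        s = sign()
        kam.add_edge(CausalEdge(root, leaf, s))
        return _SIGN_DIR[s * _DIR_SIGN[direction]]

    # exactly shared change core, split round-robin over the common roots
    shared_core: set[tuple[KamNode, Direction]] = set()
    for i, leaf in enumerate(take(shared_change_core)):
        root, direction = common_roots[i % shared_mechanism_size]
        shared_core.add((leaf, wire(root, direction, leaf)))

    # per-experiment extra common-driven changes (disjoint leaf pools)
    exp_names = [f"exp{k + 1}" for k in range(n_experiments)]
    extra_common: dict[str, set[tuple[KamNode, Direction]]] = {}
    for k, name in enumerate(exp_names):
        pairs = set()
        for i, leaf in enumerate(take(extra_common_per_experiment)):
            root, direction = common_roots[(i + k) % shared_mechanism_size]
            pairs.add((leaf, wire(root, direction, leaf)))
        extra_common[name] = pairs

    # downstream-but-never-changed filler keeps P > Q realistic
    for root, direction in common_roots:
        for leaf in take(filler_per_root):
            wire(root, direction, leaf)

    private_roots: dict[str, tuple[KamNode, ...]] = {}
    private_changes: dict[str, set[tuple[KamNode, Direction]]] = {}
    for name in exp_names:
        roots = []
        pairs: set[tuple[KamNode, Direction]] = set()
        for j in range(private_mechanism_size):
            root = KamNode(f"PR_{name}_{j}", Aspect.PROTEIN_ACTIVITY)
            kam.add_node(root)
            direction = (
                Direction.INCREASE if rng.random() < 0.5 else Direction.DECREASE
            )
            roots.append(root)
            for leaf in take(private_block):
                pairs.add((leaf, wire(root, direction, leaf)))
        private_roots[name] = tuple(roots)
        private_changes[name] = pairs

    background: dict[str, set[tuple[KamNode, Direction]]] = {}
    for name in exp_names:
        pairs = set()
        for leaf in take(n_background):
            d = Direction.INCREASE if rng.random() < 0.5 else Direction.DECREASE
            pairs.add((leaf, d))
        background[name] = pairs

    universe = frozenset(leaves)
    experiments = []
    for name in exp_names:
        changes = dict(shared_core)
        changes.update(dict(extra_common[name]))
        changes.update(dict(private_changes[name]))
        changes.update(dict(background[name]))
        experiments.append((name, universe, changes))

    return MultiExperimentFixture(
        kam=kam,
        experiments=experiments,
        common_roots=tuple(common_roots),
        private_roots=private_roots,
        shared_core=shared_core,
        expected_coverage_fraction=n_common_driven / per_exp_total,
    )
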