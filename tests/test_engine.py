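"""Hypothesis composition and the Richness/Concordance statistics."""

import pytest

import oracles
from conftest import make_kam, node, random_kam
from causalrca.engine import (
    Polarity,
    Tier,
    classify_tier,
    compose_hypothesis,
    concordance_p,
    evaluate_all,
    hypothesis_table,
    prediction_detail,
    richness_p,
    select_direction,
)
from causalrca.quantify import Direction


class TestRichness:
    def test_zero_overlap_is_one(self):
        assert richness_p(0, 30, 10, 5) == 1.0

    def test_exact_top_cell(self):
        assert richness_p(4, 10, 5, 4) == pytest.approx(5 / 210, abs=1e-14)

    def test_exact_partial_tail(self):
        expected = oracles.hypergeom_upper_tail(2, 10, 5, 4)
        assert expected == pytest.approx(0.738095238, abs=1e-9)
        assert richness_p(2, 10, 5, 4) == pytest.approx(expected, abs=1e-12)

    def test_rejects_inconsistent_counts(self):
        with pytest.raises(ValueError):
            richness_p(5, 10, 4, 4)  # Q > min(M, P)
        with pytest.raises(ValueError):
            richness_p(1, 10, 11, 2)  # M > N

    def test_strictly_positive(self):
        assert richness_p(40, 60, 40, 40) > 0


class TestConcordance:
    def test_unanimous_five(self):
        assert concordance_p(0, 5) == pytest.approx(0.03125, abs=1e-14)

    def test_split_pair(self):
        assert concordance_p(1, 1) == pytest.approx(0.75, abs=1e-14)

    def test_empty_evidence_is_one(self):
        assert concordance_p(0, 0) == 1.0

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            concordance_p(-1, 3)

    def test_adding_correct_prediction_never_hurts(self):
        for j in range(6):
            for k in range(j, 12):
                assert concordance_p(j, k + 1) <= concordance_p(j, k) + 1e-15


class TestDirectionAndTier:
    @pytest.mark.parametrize(
        "j,k,direction,tie",
        [(2, 4, Direction.INCREASE, False),
         (4, 2, Direction.DECREASE, False),
         (3, 3, Direction.INCREASE, True)],
    )
    def test_select_direction(self, j, k, direction, tie):
        assert select_direction(j, k) == (direction, tie)

    @pytest.mark.parametrize(
        "rich,conc,tier",
        [(0.04, 0.04, Tier.SIGNIFICANT),
         (0.04, 0.09, Tier.MARGINAL),
         (0.04, 0.5, Tier.NOT_SIGNIFICANT),
         (0.05, 0.05, Tier.SIGNIFICANT),  # cutoffs inclusive
         (0.2, 0.01, Tier.NOT_SIGNIFICANT)],
    )
    def test_classify_tier(self, rich, conc, tier):
        assert classify_tier(rich, conc) == tier


def star_kam(n_leaves=6):
    return make_kam(*[("A.act", f"G{i}.rna", +1) for i in range(n_leaves)])


class TestCompose:
    def test_single_consistent_edge(self):
        kam = make_kam(("A.act", "B.rna", +1))
        hyp = compose_hypothesis(
            kam, node("A.act"), {node("B.rna")},
            {node("B.rna"): Direction.INCREASE}, depth=1,
        )
        assert (hyp.N, hyp.M, hyp.P, hyp.Q, hyp.K, hyp.J) == (1, 1, 1, 1, 1, 0)

    def test_contradictory_edges_are_ambiguous(self):
        kam = make_kam(("A.act", "B.rna", +1), ("A.act", "B.rna", -1))
        hyp = compose_hypothesis(
            kam, node("A.act"), {node("B.rna")},
            {node("B.rna"): Direction.INCREASE}, depth=1,
        )
        assert hyp.predictions[0].polarity == Polarity.AMBIGUOUS
        assert (hyp.Q, hyp.K, hyp.J) == (1, 0, 0)

    def test_star_counts(self):
        kam = star_kam(6)
        universe = {node(f"G{i}.rna") for i in range(19)} | {node("X.rna")}
        changes = {node(f"G{i}.rna"): Direction.INCREASE for i in range(4)}
        changes |= {node(f"G{i}.rna"): Direction.DECREASE for i in (4, 5)}
        changes |= {node(f"G{i}.rna"): Direction.INCREASE for i in (10, 11)}
        hyp = compose_hypothesis(kam, node("A.act"), universe, changes, depth=1)
        assert (hyp.N, hyp.M, hyp.P, hyp.Q, hyp.K, hyp.J) == (20, 8, 6, 6, 4, 2)
        expected = oracles.count_hypothesis(
            oracles.kam_edge_triples(kam), node("A.act").label, 1,
            {n.label for n in universe},
            {n.label: +1 if d == Direction.INCREASE else -1
             for n, d in changes.items()},
        )
        assert expected == {"N": 20, "M": 8, "P": 6, "Q": 6, "J": 2, "K": 4}

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            compose_hypothesis(star_kam(), node("A.act"), set(), {}, 1)

    def test_changed_node_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            compose_hypothesis(
                star_kam(), node("A.act"), {node("G0.rna")},
                {node("G9.rna"): Direction.INCREASE}, 1,
            )

    def test_counts_match_path_oracle_on_random_graphs(self, rng):
        for _ in range(30):
            kam = random_kam(rng, n_nodes=int(rng.integers(4, 13)))
            nodes = sorted(kam.nodes)
            roots = [n for n in nodes if kam.adjacency().get(n)]
            if not roots:
                continue
            root = roots[int(rng.integers(len(roots)))]
            universe = {n for n in nodes if n != root and rng.random() < 0.8}
            if not universe:
                continue
            changes = {
                n: Direction.INCREASE if rng.random() < 0.5 else Direction.DECREASE
                for n in universe if rng.random() < 0.4
            }
            depth = int(rng.integers(1, 5))
            hyp = compose_hypothesis(kam, root, universe, changes, depth)
            expected = oracles.count_hypothesis(
                oracles.kam_edge_triples(kam), root.label, depth,
                {n.label for n in universe},
                {n.label: +1 if d == Direction.INCREASE else -1
                 for n, d in changes.items()},
            )
            got = {"N": hyp.N, "M": hyp.M, "P": hyp.P,
                   "Q": hyp.Q, "J": hyp.J, "K": hyp.K}
            assert got == expected


class TestInvariants:
    def _random_case(self, rng):
        kam = random_kam(rng, n_nodes=10)
        roots = [n for n in sorted(kam.nodes) if kam.adjacency().get(n)]
        root = roots[int(rng.integers(len(roots)))]
        universe = {n for n in sorted(kam.nodes) if n != root}
        changes = {
            n: Direction.INCREASE if rng.random() < 0.5 else Direction.DECREASE
            for n in universe if rng.random() < 0.4
        }
        return kam, root, universe, changes

    def test_direction_symmetry(self, rng):
        flip = {Direction.INCREASE: Direction.DECREASE,
                Direction.DECREASE: Direction.INCREASE}
        for _ in range(20):
            kam, root, universe, changes = self._random_case(rng)
            fwd = compose_hypothesis(kam, root, universe, changes, 3)
            rev = compose_hypothesis(
                kam, root, universe,
                {n: flip[d] for n, d in changes.items()}, 3,
            )
            assert (fwd.J, fwd.K) == (rev.K, rev.J)
            assert fwd.richness_p == rev.richness_p
            assert fwd.concordance_p == rev.concordance_p
            if fwd.J != fwd.K:
                assert fwd.direction != rev.direction

    def test_richness_is_direction_free(self, rng):
        for _ in range(10):
            kam, root, universe, changes = self._random_case(rng)
            if not changes:
                continue
            base = compose_hypothesis(kam, root, universe, changes, 3)
            nodes = list(changes)
            directions = [changes[n] for n in nodes]
            rng.shuffle(directions)
            permuted = dict(zip(nodes, directions))
            perm = compose_hypothesis(kam, root, universe, permuted, 3)
            assert perm.Q == base.Q
            assert perm.richness_p == base.richness_p

    def test_ambiguous_predictions_count_in_q_not_jk(self, rng):
        for _ in range(20):
            kam, root, universe, changes = self._random_case(rng)
            hyp = compose_hypothesis(kam, root, universe, changes, 3)
            n_ambiguous_changed = sum(
                1 for p in hyp.predictions
                if p.polarity == Polarity.AMBIGUOUS and p.node in changes
            )
            assert hyp.J + hyp.K == hyp.Q - n_ambiguous_changed


class TestEvaluateAll:
    def make_case(self):
        kam = star_kam(5)
        universe = {node(f"G{i}.rna") for i in range(5)} | {
            node(f"X{i}.rna") for i in range(95)
        }
        changes = {node(f"G{i}.rna"): Direction.INCREASE for i in range(5)}
        return kam, universe, changes

    def test_perfect_star_scores_exactly(self):
        kam, universe, changes = self.make_case()
        (hyp,) = evaluate_all(kam, universe, changes, depth=1)
        assert hyp.root == node("A.act")
        assert hyp.richness_p == pytest.approx(1 / 75287520, rel=1e-9)
        assert hyp.concordance_p == pytest.approx(0.03125, abs=1e-14)
        assert hyp.direction == Direction.INCREASE
        assert hyp.tier == Tier.SIGNIFICANT

    def test_flipped_observations_flip_direction_only(self):
        kam, universe, changes = self.make_case()
        flipped = {n: Direction.DECREASE for n in changes}
        (fwd,) = evaluate_all(kam, universe, changes, depth=1)
        (rev,) = evaluate_all(kam, universe, flipped, depth=1)
        assert rev.richness_p == fwd.richness_p
        assert rev.concordance_p == fwd.concordance_p
        assert rev.direction == Direction.DECREASE

    def test_empty_change_set_scores_nothing(self):
        kam, universe, _ = self.make_case()
        (hyp,) = evaluate_all(kam, universe, {}, depth=1)
        assert hyp.Q == 0
        assert hyp.richness_p == 1.0
        assert hyp.tier == Tier.NOT_SIGNIFICANT

    def test_ranking_is_deterministic(self, rng):
        kam = random_kam(rng, n_nodes=12)
        universe = set(kam.nodes)
        changes = {
            n: Direction.INCREASE for n in sorted(universe) if rng.random() < 0.3
        }
        a = evaluate_all(kam, universe, changes, 2)
        b = evaluate_all(kam, universe, changes, 2)
        assert [h.root for h in a] == [h.root for h in b]


class TestReports:
    def test_hypothesis_table_columns(self):
        kam = star_kam(5)
        universe = {node(f"G{i}.rna") for i in range(5)}
        changes = {node("G0.rna"): Direction.INCREASE}
        table = hypothesis_table(evaluate_all(kam, universe, changes, 1))
        assert list(table.columns) == [
            "root_entity", "root_aspect", "direction", "tie",
            "N", "M", "P", "Q", "J", "K",
            "richness_p", "concordance_p", "tier",
        ]

    def test_prediction_detail_flags_inconsistent_rows(self):
        kam = make_kam(("A.act", "B.rna", +1), ("A.act", "C.rna", +1),
                       ("A.act", "D.rna", +1))
        universe = {node("B.rna"), node("C.rna"), node("D.rna")}
        changes = {node("B.rna"): Direction.INCREASE,
                   node("C.rna"): Direction.INCREASE,
                   node("D.rna"): Direction.DECREASE}
        (hyp,) = evaluate_all(kam, universe, changes, 1)
        detail = prediction_detail(hyp, changes)
        flags = dict(zip(detail["node"], detail["consistent"]))
        assert flags == {"B.rna_abundance": "", "C.rna_abundance": "",
                         "D.rna_abundance": "X"}
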