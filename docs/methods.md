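# Methods

## Model and procedure

The package implements reverse causal analysis on a signed causal knowledge
graph.  Nodes are `(entity, aspect)` pairs with aspects drawn from a fixed
vocabulary (`rna_abundance`, `protein_abundance`, `protein_activity`,
`protein_modification`, `compound`, `process`); edges are signed cause→effect
assertions, optionally carrying citations and a species-of-origin tag
(human assertions augmented with rat/mouse orthologs).  Contradictory edge
pairs (both signs between one source and one target) are legal content:
they are the mechanism that makes downstream polarity ambiguous.  Self-loops
are rejected at load time, and duplicate `(source, target, sign)` rows merge
their evidence, so loading is order-independent.

A hypothesis is a node assumed *increased*.  Its predictions are the
measured nodes reachable by directed **simple** paths of length ≤ `depth`
(default 2), each labelled with the set of attainable path-sign products:
`{+1}` → increase, `{−1}` → decrease, `{+1, −1}` → ambiguous.  Simple paths
(no repeated node within a path) keep the search finite on cyclic graphs and
match the bounded-steps intent; depth 2 admits activity → activity →
expression chains while staying tractable, and is configurable.

Scoring uses two inclusive upper-tail p-values.  Richness is
Pr[X ≥ Q] for X ~ Hypergeometric(N, M, P): population the N measured nodes,
M observed changes, P predictions, Q predicted-and-changed.  It is
direction-blind, so ambiguous predictions contribute to Q.  Concordance is
Pr[X ≥ H] for X ~ Binomial(J + K, ½) with H = max(J, K), where K and J count
unambiguous predictions agreeing with an increased or decreased root;
ambiguous predictions contribute to neither.  Q = 0 and J + K = 0 return
exactly 1.  The root's reported direction is the better-supported one; a
J = K tie is reported as increase with an explicit tie flag rather than
dropped, so the hypothesis stays inspectable.  A hypothesis is significant
when both p-values are ≤ 0.05, marginally significant at ≤ 0.1; the cutoffs
are applied raw (an optional BH-over-hypotheses mode exists but is off by
default, matching the raw-cutoff regime these scores were designed for).
Ranking is deterministic: tier, then concordance, richness, Q descending,
root id.

Only measured nodes enter N, P and Q.  Measured entities absent from the
graph still count in N — they were measurements even if no assertion covers
them — and M is defined on observations, so a change reachable only beyond
the search depth still counts toward M.

## Quantification

Expression matrices are log2 scale.  The two-group test is the
pooled-variance Student t, which for two groups is exactly the one-way
ANOVA F-test (F = t² on 1 and n₁+n₂−2 df); `one_way_anova` is available for
multi-group designs, and multi-timepoint pooling is expressed through the
design (all pooled samples share a group label).  A variance floor
(ε = 1e−9 added to the pooled variance) keeps exact-replicate fixtures
finite: such genes get p ≈ 0 when the means differ, and genes with exactly
equal group means get p = 1 by convention.  Linear fold change is
2^(mean_treated − mean_control); the fold criterion applies to
max(r, 1/r).  Default calling regime: BH-adjusted p ≤ 0.05 and fold ≥ 1.3;
the permissive regime (raw p ≤ 0.01, no fold criterion) serves comparisons
dominated by many modest fold changes.  The two regimes are *not* strictly
nested — BH's step-up threshold is data-dependent and can exceed 0.01 when
many genes change — but each regime is monotone in its own thresholds:
raising the p cutoff or lowering the fold cutoff never removes a call.

Phospho ratios use asymmetric inclusive thresholds: ratio ≤ 0.80 is a
decrease, ≥ 1.50 an increase.  Because 1 − 0.20 is not exactly the double
0.80, the comparison carries a 1e−9 absolute slack so a ratio written as
"0.80" is boundary-inclusive.  When the RNA and phospho streams (or two
timepoints) disagree about one node's direction, the node is dropped with a
logged warning — conservative for concordance, which would otherwise count
an arbitrary winner.

## Cross-experiment assembly

A mechanism enters the Causal Network Model only if it meets the tier floor
with a consistent direction in every experiment.  A changed node is
*explained* when at least one selected root unambiguously predicts its
observed direction and none predicts the opposite; *contradicted* when only
opposite predictions reach it; *conflicted* when selected roots disagree.
Coverage fractions are explained/total changes.  The exported subgraph
unions inter-root simple paths (length ≤ depth) with root→explained-change
paths.  The published method's remaining selection criteria involve
scientist judgment; they are surfaced as computable per-root flags
(downstream of the designated perturbation node, connected to other roots,
root entity itself a state change) rather than automated decisions.

## Synthetic benchmarks

`generate_kam` builds a layered signed DAG: 25% of the regulator activities
form an upstream layer wired to 3 downstream regulators each; downstream
regulators wire to 8 RNA leaves each; edge signs invert with probability
0.3, and each edge gains an opposite-sign twin with probability 0.02.  The
layered DAG keeps ground-truth polarity well-defined (the generator derives
expected leaf directions by its own forward sign relaxation, independent of
the engine's path search, and the two are cross-checked in tests); random
cyclic graphs are used separately to stress the path search, where no
direction ground truth exists.  Defaults — 200 regulator entities, 120
leaves, linear fold 2.0, log2 noise sd 0.25 (tight RMA-style replicates),
4 replicates/group, 1% background change rate — are the study conditions for
every recovery and calibration result; expression noise is log2-normal with
planted mean shifts, the simplest model consistent with RMA-scale data.
Phosphosubstrates of an inhibited planted kinase draw ratios in
(0.40, 0.70), of an activated one in (1.60, 2.20), and otherwise in
(0.90, 1.10).  All randomness flows from one seeded generator per call; no
global state.

Under these conditions the calibrated RNA state-change sensitivity is ≈ 0.91,
not higher: the noncentral-t power at the BH plug-in threshold
(raw-p ≈ (m₁/m)·0.05 ≈ 0.009, df 6, noncentrality log2(2)/(0.25·√½) ≈ 5.66)
is 0.914, and the suite asserts the simulation against that calibration with
a 3σ sampling margin.  Recovery of the *planted root* is far more robust
than per-gene sensitivity — the root aggregates evidence over its whole
downstream neighbourhood — which is why top-5 recovery is essentially
perfect across seeds while individual borderline genes are missed.

The multi-experiment fixture plants shared mechanisms behind mostly
non-overlapping gene responses: 4 common roots drive 28 of each
experiment's 84 changes (exactly one-third), including a 17-pair change
core shared identically by all experiments; 2 private roots per experiment
drive 10 changes each, plus 36 background changes, inside a measured
universe of 1000 leaves.  Core, per-experiment and background changes are
drawn from disjoint leaf blocks, so the full intersection equals the core
exactly and the coverage arithmetic is closed-form — the fixture tests
bookkeeping, not statistics.  The large unchanged universe is what makes
each common root's per-experiment richness decisive (P ≈ 16 predictions,
Q ≈ 7 changed, against an expectation of ≈ 1.3).

## What the synthetic data does not show

The generator emulates the statistical structure the method assumes — a
signed graph whose causal claims are true, downstream transcript shifts of
uniform magnitude, independent lognormal noise — and none of the ways real
data violate it: no probe-level artifacts or batch structure, no correlated
noise, no hub-dominated literature-bias topologies, no wrong or missing
assertions, and effect sizes that are homogeneous rather than long-tailed.
Passing recovery tests therefore demonstrates correctness of the machinery
and its calibration under the stated model, not performance on real
knowledge bases, where edge quality and coverage dominate.

## Numerical and interface choices

Hypergeometric and binomial tails come from scipy; tests verify them to
1e−12 against exact integer enumeration over the full support (all N ≤ 60).
BH adjustment is statsmodels' `fdr_bh`, verified against an independent
step-up implementation.  All tables are written with stable column order
and sorted rows so repeated runs are byte-identical.  Two graph dialects
are read and written: a seven-column TSV with explicit aspects, species and
;-joined evidence, and a three-column signed-SIF with dotted
`ENTITY.aspect` labels (short aliases `act`, `rna`, `prot`, `mod`, `cmpd`
accepted).  Degenerate inputs have defined behaviour: empty graphs and
empty change sets produce empty-but-valid reports, an empty prediction set
scores 1.0 on both statistics, and malformed files fail with the offending
line and token named.

## Known limitations

Simple-path enumeration is exponential in depth on dense graphs; the
default depth of 2 keeps it linear-ish in edge count, but depths ≥ 4 on
highly connected graphs are expensive.  The engine carries no
multiple-testing control across the thousands of hypotheses a large graph
yields (by design, matching the raw-cutoff regime); the optional BH mode is
a blunt instrument because hypotheses are strongly dependent through shared
downstream neighbourhoods.  Orthologous assertions are carried as metadata
only — no orthology inference.  The CNM's judgment-based selection criteria
are reported as flags, not decided.
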