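# causalrca

Reverse causal analysis (RCA) for omics data: given a literature-style
**signed causal knowledge graph** and a set of observed molecular **state
changes** (differential RNA abundances, phosphoprotein ratios), score every
graph node as a candidate *upstream mechanism* — "what, if increased or
decreased, would explain what we measured?" — and merge the mechanisms that
hold up across experiments into a single **Causal Network Model** (CNM) with
explicit explanatory coverage.

The package is aimed at computational biologists analysing perturbation
experiments (drug treatments, knockdowns) who want mechanistic hypotheses
ranked by statistical merit rather than gene lists, and at methodologists who
need a fully synthetic, ground-truthed benchmark for this class of
upstream-regulator methods.

## The method

The knowledge substrate is a directed graph whose nodes are `(entity,
aspect)` pairs — the *kinase activity* of AKT1 is a different node from the
*RNA abundance* of AKT1 — and whose edges carry a sign: noninverting (+1,
"increases") or inverting (−1, "decreases").

**Quantification.** Replicate log2 expression matrices are reduced per gene
to `increase` / `decrease` / `no_change` by a two-group test (pooled-variance
t, identically the two-group one-way ANOVA F) with Benjamini–Hochberg FDR
≤ 0.05 and linear fold change ≥ 1.3 by default; a permissive regime
(unadjusted p ≤ 0.01, no fold criterion) is available for comparisons with
many modest fold changes. Phosphoprotein treated/vehicle ratios are
thresholded asymmetrically: ≤ 0.80 is a decrease, ≥ 1.50 an increase.

**Hypothesis scoring.** Each node is assumed *increased* and the graph is
searched a bounded number of causal steps downstream (directed simple paths,
default depth 2). Every measured node reached is a *prediction* with
polarity given by the product of edge signs along the paths — `ambiguous`
when contradictory paths exist. With

- `N` measured nodes, `M` observed changes, `P` predictions,
- `Q` nodes both predicted and changed,
- `K` / `J` changes supporting an increased / decreased root,

two upper-tail p-values score the hypothesis:

- **Richness** = Pr[X ≥ Q], X ~ Hypergeometric(N, M, P) — are observed
  changes over-represented among the predictions? (direction-blind, so
  ambiguous predictions count);
- **Concordance** = Pr[X ≥ H], X ~ Binomial(J + K, ½), H = max(J, K) — do
  the unambiguous predictions agree with the observed directions more than
  chance?

The reported root direction is the one explaining more changes. A
hypothesis is *significant* when both p-values are ≤ 0.05 and *marginally
significant* at ≤ 0.1.

**Assembly.** Across experiments, only roots significant with a consistent
direction in *every* experiment survive; the merged subgraph of those roots,
their inter-root causal paths and their explained changes forms the CNM,
with per-experiment counts of explained / contradicted / conflicted changes.

## Worked example

Generate a planted benchmark (200 regulator activities in two layers, 120
RNA leaves, the kinase activity `U001` planted as *decreased*, fold 2.0,
log2 noise sd 0.25, n = 4/group), call state changes, and score hypotheses:

```sh
causalrca simulate --out-dir demo --seed 11 \
    --planted-root U001 --planted-direction decrease
causalrca quantify --matrix demo/expression.tsv --design demo/design.tsv \
    --phospho demo/phospho.tsv --out demo/changes.tsv
causalrca rca --kam demo/kam.tsv --changes demo/changes.tsv \
    --out demo/hypotheses.tsv
```

which logs

```
INFO causalrca: wrote benchmark with 325 nodes, 23 planted downstream changes
INFO causalrca: experiment: 125 measured, 32 changed (13 increase / 19 decrease), 0 conflicts dropped
INFO causalrca: 200 hypotheses scored (7 significant)
```

and the top of `demo/hypotheses.tsv` reads

```
root_entity  root_aspect       direction  tie    N    M   P   Q   J   K   richness_p  concordance_p  tier
U001         protein_activity  decrease   False  125  32  28  28  28  0   5.60e-24    3.73e-09       significant
U041         protein_activity  decrease   False  125  32  22  12  12  0   1.31e-03    2.44e-04       significant
```

The planted root ranks first: 28 of its 28 measured downstream predictions
changed (Q = 28 of P = 28), all in the direction implied by a *decreased*
root (J = 28, K = 0), so both figures of merit are vanishingly small.  The
runners-up are upstream regulators that genuinely share part of the planted
root's downstream neighbourhood.  The same library calls are available in
Python (`generate_kam`, `simulate_expression`, `call_rna_state_changes`,
`evaluate_all`, `common_hypotheses`, `assemble_cnm`).

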