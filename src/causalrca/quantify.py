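"""Quantify omics measurements into signed state changes.

Expression matrices (log2 scale, genes × samples, with a treated/control
design) are reduced per gene to one of ``increase`` / ``decrease`` /
``no_change`` by a differential test plus fold-change rule; phosphoprotein
treated/vehicle ratio tables are reduced by fixed asymmetric thresholds
(a 20% decrease or a 50% increase counts as changed).  Both streams emit
:class:`StateChange` records keyed by knowledge-graph nodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .kam import Aspect, KamNode

__all__ = [
    "Direction",
    "StateChange",
    "ChangeCriteria",
    "DEFAULT_RNA_CRITERIA",
    "PERMISSIVE_UNADJUSTED_CRITERIA",
    "ExpressionExperiment",
    "PhosphoRatioTable",
    "bh_adjust",
    "call_rna_state_changes",
    "call_phospho_state_changes",
    "merge_state_changes",
    "read_expression",
    "read_phospho_table",
    "write_state_changes",
    "read_state_changes",
]

log = logging.getLogger(__name__)

#: Pooled-variance floor so exactly-replicated fixtures do not divide by zero;
#: a gene with zero within-group variance and unequal means gets p ~ 0.
_VAR_EPS = 1e-9

#: Absolute slack for the phospho ratio thresholds, so a ratio written as
#: "0.80" is boundary-inclusive despite binary rounding of 1 - 0.20.
_RATIO_TOL = 1e-9


class Direction(str, Enum):
    INCREASE = "increase"
    DECREASE = "decrease"
    NO_CHANGE = "no_change"


@dataclass(frozen=True)
class StateChange:
    """One measured entity mapped to a ternary call with its statistics.

    ``fold_change`` is the linear treated/control ratio (``2**Δlog2``); it is
    > 1 for increases and < 1 for decreases.  Phospho calls carry the raw
    ratio and no p-values.
    """

    node: KamNode
    direction: Direction
    fold_change: float
    p_raw: float | None = None
    p_adjusted: float | None = None

    def __post_init__(self) -> None:
        if self.direction == Direction.INCREASE and not self.fold_change > 1:
            raise ValueError("increase requires fold_change > 1")
        if self.direction == Direction.DECREASE and not self.fold_change < 1:
            raise ValueError("decrease requires fold_change < 1")

    @property
    def changed(self) -> bool:
        return self.direction != Direction.NO_CHANGE


@dataclass(frozen=True)
class ChangeCriteria:
    """Significance rule for expression calls.

    ``p_mode`` selects Benjamini-Hochberg adjusted or raw p-values;
    ``min_abs_fold_change`` (linear scale, applied to ``max(r, 1/r)``) may be
    ``None`` to disable the fold criterion.
    """

    p_mode: str = "adjusted_bh"
    p_cutoff: float = 0.05
    min_abs_fold_change: float | None = 1.3

    def __post_init__(self) -> None:
        if self.p_mode not in ("adjusted_bh", "unadjusted"):
            raise ValueError(f"unknown p_mode {self.p_mode!r}")
        if not 0 < self.p_cutoff < 1:
            raise ValueError("p_cutoff must be in (0, 1)")
        if self.min_abs_fold_change is not None and self.min_abs_fold_change < 1:
            raise ValueError("min_abs_fold_change must be >= 1")


#: BH-adjusted p <= 0.05 plus |fold| >= 1.3 — the stringent regime.
DEFAULT_RNA_CRITERIA = ChangeCriteria("adjusted_bh", 0.05, 1.3)
#: Raw p <= 0.01, no fold criterion — the permissive regime used when a
#: comparison produces too many large fold changes for the stringent rule.
PERMISSIVE_UNADJUSTED_CRITERIA = ChangeCriteria("unadjusted", 0.01, None)


@dataclass
class ExpressionExperiment:
    """A log2 expression matrix plus its treated/control design."""

    matrix: pd.DataFrame  # genes x samples
    design: pd.Series  # sample -> group label
    name: str = "experiment"

    def __post_init__(self) -> None:
        self.design = pd.Series(self.design)
        if self.matrix.index.hasnans or (self.matrix.index == "").any():
            raise ValueError("missing gene identifiers in matrix index")
        if self.matrix.index.duplicated().any():
            dups = self.matrix.index[self.matrix.index.duplicated()].unique()
            raise ValueError(f"duplicate gene rows: {list(dups)[:5]}")
        missing = set(self.matrix.columns) - set(self.design.index)
        if missing:
            raise ValueError(f"samples without design annotation: {sorted(missing)}")
        counts = self.design.loc[list(self.matrix.columns)].value_counts()
        if len(counts) < 2 or (counts < 2).any():
            raise ValueError(
                "each design group needs >= 2 replicate samples; got "
                + ", ".join(f"{g}: {c}" for g, c in counts.items())
            )

    def group_columns(self, group: str) -> list[str]:
        return [s for s in self.matrix.columns if self.design[s] == group]


@dataclass
class PhosphoRatioTable:
    """Treated/vehicle phosphoprotein ratios per analyte and timepoint."""

    table: pd.DataFrame  # columns: entity, modification, timepoint, ratio
    name: str = "phospho"

    def __post_init__(self) -> None:
        required = {"entity", "modification", "timepoint", "ratio"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"phospho table lacks columns: {sorted(missing)}")
        ratios = self.table["ratio"].to_numpy(float)
        if not np.all(ratios > 0):
            bad = self.table.loc[~(self.table["ratio"] > 0)]
            raise ValueError(
                f"non-positive phospho ratio(s), e.g. row {bad.index[0]}"
            )


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _pooled_t(treated: np.ndarray, control: np.ndarray) -> np.ndarray:
    """Vectorised pooled-variance (Student) t-test p-values, rows = genes.

    For a two-group design this is exactly the one-way ANOVA F-test
    (F = t**2 on 1 and n1+n2-2 df).  A variance floor keeps exact-replicate
    fixtures finite; equal means give t = 0 and hence p = 1 regardless of
    variance.
    """
    n1, n2 = treated.shape[1], control.shape[1]
    m1, m2 = treated.mean(axis=1), control.mean(axis=1)
    v1 = treated.var(axis=1, ddof=1)
    v2 = control.var(axis=1, ddof=1)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df + _VAR_EPS
    t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return 2.0 * stats.t.sf(np.abs(t), df)


def _anova_p(groups: list[np.ndarray]) -> np.ndarray:
    """Vectorised one-way fixed-effects ANOVA p-values, rows = genes."""
    k = len(groups)
    ns = np.array([g.shape[1] for g in groups])
    n_total = int(ns.sum())
    grand = np.hstack(groups).mean(axis=1)
    means = np.stack([g.mean(axis=1) for g in groups])
    ss_between = (ns[:, None] * (means - grand) ** 2).sum(axis=0)
    ss_within = sum(
        ((g - m[:, None]) ** 2).sum(axis=1) for g, m in zip(groups, means)
    )
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (n_total - k) + _VAR_EPS
    f = ms_between / ms_within
    return stats.f.sf(f, k - 1, n_total - k)


def call_rna_state_changes(
    experiment: ExpressionExperiment,
    criteria: ChangeCriteria = DEFAULT_RNA_CRITERIA,
    test: str = "two_sample_t",
    treated_group: str = "treated",
    control_group: str = "control",
) -> list[StateChange]:
    """Ternary call per gene from a replicate log2 expression matrix.

    A gene is *changed* iff its p-value (adjusted or raw per ``criteria``)
    is <= the cutoff and, when a fold criterion is present, its linear fold
    change satisfies ``max(r, 1/r) >= min_abs_fold_change``.  Direction
    follows the sign of the mean log2 difference.  One record per gene is
    returned (unchanged genes get ``no_change``), mapped to
    ``rna_abundance`` nodes.
    """
    treated = experiment.matrix[experiment.group_columns(treated_group)].to_numpy(float)
    control = experiment.matrix[experiment.group_columns(control_group)].to_numpy(float)
    if treated.shape[1] < 2 or control.shape[1] < 2:
        raise ValueError("both groups need >= 2 replicates")

    if test == "two_sample_t":
        p_raw = _pooled_t(treated, control)
    elif test == "one_way_anova":
        groups = [
            experiment.matrix[experiment.group_columns(g)].to_numpy(float)
            for g in pd.unique(experiment.design.loc[list(experiment.matrix.columns)])
        ]
        p_raw = _anova_p(groups)
    else:
        raise ValueError(f"unknown test {test!r}")

    diff = treated.mean(axis=1) - control.mean(axis=1)
    # identical groups: no evidence of change by convention
    p_raw = np.where(diff == 0, 1.0, p_raw)
    p_adj = bh_adjust(p_raw)
    p_eff = p_adj if criteria.p_mode == "adjusted_bh" else p_raw

    ratio = np.exp2(diff)
    abs_fold = np.maximum(ratio, 1.0 / ratio)
    passes = p_eff <= criteria.p_cutoff
    if criteria.min_abs_fold_change is not None:
        passes &= abs_fold >= criteria.min_abs_fold_change
    passes &= diff != 0

    out: list[StateChange] = []
    for gene, ok, r, d, pr, pa in zip(
        experiment.matrix.index, passes, ratio, diff, p_raw, p_adj
    ):
        if ok:
            direction = Direction.INCREASE if d > 0 else Direction.DECREASE
        else:
            direction = Direction.NO_CHANGE
        out.append(
            StateChange(
                KamNode(str(gene), Aspect.RNA_ABUNDANCE),
                direction,
                float(r),
                float(pr),
                float(pa),
            )
        )
    return out


def call_phospho_state_changes(
    table: PhosphoRatioTable,
    decrease_threshold: float = 0.20,
    increase_threshold: float = 0.50,
) -> list[StateChange]:
    """Threshold treated/vehicle ratios into ternary phospho calls.

    A ratio at or below ``1 - decrease_threshold`` (default 0.80) is a
    decrease; at or above ``1 + increase_threshold`` (default 1.50) an
    increase; anything between is no change.  The asymmetry is deliberate:
    0.80 calls decrease while its reciprocal 1.25 is no change.  Nodes carry
    the ``protein_modification`` aspect; p-value fields stay unset.
    """
    lower = 1.0 - decrease_threshold
    upper = 1.0 + increase_threshold
    out: list[StateChange] = []
    for row in table.table.itertuples(index=False):
        ratio = float(row.ratio)
        if ratio <= 0:
            raise ValueError(f"non-positive ratio {ratio} for {row.entity}")
        if ratio <= lower + _RATIO_TOL:
            direction = Direction.DECREASE
        elif ratio >= upper - _RATIO_TOL:
            direction = Direction.INCREASE
        else:
            direction = Direction.NO_CHANGE
        out.append(
            StateChange(
                KamNode(str(row.entity), Aspect.PROTEIN_MODIFICATION),
                direction,
                ratio,
            )
        )
    return out


def merge_state_changes(
    rna: Iterable[StateChange], phospho: Iterable[StateChange] = ()
) -> tuple[list[StateChange], list[KamNode]]:
    """Union the evidence streams into one per-node state-change set.

    Repeated calls on the same node (e.g. one analyte at several timepoints)
    collapse to a single record when directions agree; nodes with
    contradictory changed directions are dropped and reported in the second
    return value.  A changed call wins over a no-change call for the same
    node.
    """
    by_node: dict[KamNode, StateChange] = {}
    conflicted: set[KamNode] = set()
    for sc in list(rna) + list(phospho):
        prev = by_node.get(sc.node)
        if prev is None:
            by_node[sc.node] = sc
        elif prev.direction == sc.direction:
            continue
        elif not prev.changed:
            by_node[sc.node] = sc
        elif sc.changed:  # both changed, opposite directions
            conflicted.add(sc.node)
    for node in conflicted:
        del by_node[node]
        log.warning("conflicting directions for %s; node dropped", node.label)
    return list(by_node.values()), sorted(conflicted)


# ---------------------------------------------------------------------------
# I/O helpers (plain TSV)
# ---------------------------------------------------------------------------


def read_expression(matrix_path, design_path, name: str = "experiment") -> ExpressionExperiment:
    """Read a ``gene`` + sample-columns matrix TSV and a ``sample group`` design TSV."""
    matrix = pd.read_csv(matrix_path, sep="\t", index_col="gene")
    design = pd.read_csv(design_path, sep="\t", index_col="sample")["group"]
    return ExpressionExperiment(matrix, design, name)


def read_phospho_table(path, name: str = "phospho") -> PhosphoRatioTable:
    return PhosphoRatioTable(pd.read_csv(path, sep="\t"), name)


def write_state_changes(changes: Iterable[StateChange], path) -> None:
    rows = [
        {
            "entity": sc.node.entity_id,
            "aspect": sc.node.aspect.value,
            "direction": sc.direction.value,
            "fold_change": sc.fold_change,
            "p_raw": "" if sc.p_raw is None else sc.p_raw,
            "p_adjusted": "" if sc.p_adjusted is None else sc.p_adjusted,
        }
        for sc in changes
    ]
    df = pd.DataFrame(
        rows,
        columns=["entity", "aspect", "direction", "fold_change", "p_raw", "p_adjusted"],
    ).sort_values(["entity", "aspect"], kind="mergesort")
    df.to_csv(path, sep="\t", index=False)


def read_state_changes(path) -> list[StateChange]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            StateChange(
                KamNode(str(row.entity), Aspect(row.aspect)),
                Direction(row.direction),
                float(row.fold_change),
                None if pd.isna(row.p_raw) else float(row.p_raw),
                None if pd.isna(row.p_adjusted) else float(row.p_adjusted),
            )
        )
    return out
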