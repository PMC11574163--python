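"""Rule-based patient stratification and between-group marker comparisons.

Strata follow the clinical-analysis rules of the study design:

* mutation status — ``Mut`` if the patient carries any non-silent mutation
  in the target gene; otherwise ``LowExpr`` if their tumor FPKM falls below
  the ``low_pct``-th percentile of non-mutant tumors (default 12); else
  ``WT``;
* expression split — median rule (ties to high), tertile rule, or a fixed
  threshold;
* marker flag — strictly above a normalized-FPKM cut (default 1.75);
* functional group — ``high_E27`` iff mutation status is WT and the
  regulator group is low; everyone else is ``low_E27``.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from splicescreen.stats import TestResult, adjust_bonferroni, anova_oneway, student_t_two_sample
from splicescreen.types import ExprMatrix, MutationRecord, VariantClass

logger = logging.getLogger(__name__)

__all__ = [
    "MutStatus",
    "ExprGroup",
    "SplitRule",
    "PatientStratum",
    "GroupComparison",
    "classify_mut_status",
    "split_by_expression",
    "flag_pdl1_high",
    "functional_group",
    "compare_marker_by_group",
]


class MutStatus(str, enum.Enum):
    WT = "WT"
    MUT = "Mut"
    LOW_EXPR = "LowExpr"


class ExprGroup(str, enum.Enum):
    HIGH = "high"
    LOW = "low"
    UNASSIGNED = "unassigned"


class SplitRule(str, enum.Enum):
    MEDIAN = "median"
    TERTILE = "tertile"
    THRESHOLD = "threshold"


@dataclass(frozen=True)
class PatientStratum:
    patient_id: str
    mut_status: MutStatus
    psi_group: ExprGroup = ExprGroup.UNASSIGNED
    regulator_group: ExprGroup = ExprGroup.UNASSIGNED
    pdl1_high: bool = False
    functional_group: str = "low_E27"


@dataclass(frozen=True)
class GroupComparison:
    marker: str
    groups: tuple[str, ...]
    group_means: tuple[float, ...]
    test: str
    p_values: tuple[float, ...]  # per contrast (single entry for two groups)
    contrasts: tuple[str, ...]
    results: tuple[TestResult, ...]


def _tumor_expr(expr: ExprMatrix, gene: str, tumor_sample_of: dict) -> pd.Series:
    """Per-patient tumor FPKM for one gene; patients without a tumor sample
    or with missing expression are dropped."""
    row = expr.row(gene)
    vals = {}
    for patient, sample in tumor_sample_of.items():
        if sample in row.index and not np.isnan(row[sample]):
            vals[patient] = float(row[sample])
    return pd.Series(vals, dtype=float)


def classify_mut_status(
    mutations: list[MutationRecord],
    expr: ExprMatrix,
    gene: str,
    tumor_sample_of: dict,
    low_pct: float = 12.0,
) -> dict:
    """Per-patient mutation class for ``gene``.

    ``tumor_sample_of`` maps patient_id -> tumor sample_id.  The LowExpr cut
    is the ``low_pct``-th percentile of the gene's tumor FPKM among
    non-mutant patients.
    """
    if gene not in expr:
        raise KeyError(f"gene {gene!r} absent from expression matrix")
    mutant = {
        m.patient_id
        for m in mutations
        if m.gene == gene and m.variant_class != VariantClass.SILENT
    }
    vals = _tumor_expr(expr, gene, tumor_sample_of)
    non_mut = vals[~vals.index.isin(mutant)]
    cut = float(np.percentile(non_mut.to_numpy(), low_pct)) if len(non_mut) else np.nan
    out: dict[str, MutStatus] = {}
    for patient in tumor_sample_of:
        if patient in mutant:
            out[patient] = MutStatus.MUT
        elif patient in vals.index and not np.isnan(cut) and vals[patient] < cut:
            out[patient] = MutStatus.LOW_EXPR
        else:
            out[patient] = MutStatus.WT
    return out


def split_by_expression(
    values: pd.Series | dict,
    rule: SplitRule | str = SplitRule.MEDIAN,
    threshold: float | None = None,
) -> dict:
    """Split patients into expression groups.

    median: >= median -> high (ties to high).  tertile: top third high,
    bottom third low, middle unassigned.  threshold: > threshold -> high.
    """
    s = pd.Series(values, dtype=float).dropna()
    if s.empty:
        raise ValueError("all values missing: cannot split")
    rule = SplitRule(rule)
    out: dict[str, ExprGroup] = {}
    if rule == SplitRule.MEDIAN:
        med = float(s.median())
        if s.nunique() == 1:
            logger.warning("constant expression: all patients 'high' under median rule")
        for k, v in s.items():
            out[k] = ExprGroup.HIGH if v >= med else ExprGroup.LOW
    elif rule == SplitRule.TERTILE:
        order = s.sort_values(kind="mergesort")
        n = len(order)
        third = n // 3
        lows = set(order.index[:third])
        highs = set(order.index[n - third :])
        for k in s.index:
            if k in highs:
                out[k] = ExprGroup.HIGH
            elif k in lows:
                out[k] = ExprGroup.LOW
            else:
                out[k] = ExprGroup.UNASSIGNED
    else:
        if threshold is None:
            raise ValueError("threshold rule requires a threshold value")
        for k, v in s.items():
            out[k] = ExprGroup.HIGH if v > threshold else ExprGroup.LOW
    return out


def flag_pdl1_high(
    expr: ExprMatrix,
    marker: str,
    tumor_sample_of: dict,
    cut: float = 1.75,
    strata: dict | None = None,
) -> tuple[dict, dict]:
    """Per-patient marker flag: strictly above ``cut`` (a value exactly at
    the cut is not flagged).

    Returns (flags, per-stratum percentages); percentages are
    ``{stratum: (percent, numerator, denominator)}`` computed over the
    optional ``strata`` labels.
    """
    vals = _tumor_expr(expr, marker, tumor_sample_of)  # raises if marker absent
    flags = {p: bool(v > cut) for p, v in vals.items()}
    percents: dict = {}
    if strata:
        groups: dict[str, list[bool]] = {}
        for p, flag in flags.items():
            label = strata.get(p)
            if label is not None:
                key = label.value if isinstance(label, enum.Enum) else str(label)
                groups.setdefault(key, []).append(flag)
        for label, fs in sorted(groups.items()):
            num = sum(fs)
            percents[label] = (100.0 * num / len(fs), num, len(fs))
    return flags, percents


def functional_group(mut_status: MutStatus, regulator_group: ExprGroup) -> str:
    """high_E27 iff target-gene WT and regulator-low; all others low_E27."""
    return (
        "high_E27"
        if mut_status == MutStatus.WT and regulator_group == ExprGroup.LOW
        else "low_E27"
    )


def compare_marker_by_group(
    values_by_group: dict,
    marker: str = "",
) -> GroupComparison:
    """Two groups: two-tailed pooled t.  More: one-way ANOVA with Bonferroni
    pairwise contrasts."""
    labels = sorted(values_by_group)
    groups = [np.asarray(values_by_group[g], dtype=float) for g in labels]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for lbl, g in zip(labels, groups):
        if len(g) < 2:
            raise ValueError(f"group {lbl!r} has fewer than 2 patients")
    means = tuple(float(g.mean()) for g in groups)

    if len(groups) == 2:
        if all(np.ptp(g) == 0 for g in groups) and means[0] == means[1]:
            res = TestResult(0.0, len(groups[0]) + len(groups[1]) - 2, 1.0, "student_t_pooled")
        else:
            res = student_t_two_sample(groups[0], groups[1])
        return GroupComparison(
            marker,
            tuple(labels),
            means,
            "t",
            (res.p_value,),
            (f"{labels[0]} vs {labels[1]}",),
            (res,),
        )

    omnibus = anova_oneway(groups)
    contrasts, raws, results = [], [], []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            try:
                r = student_t_two_sample(groups[i], groups[j])
            except ValueError:
                r = TestResult(0.0, len(groups[i]) + len(groups[j]) - 2, 1.0, "student_t_pooled")
            contrasts.append(f"{labels[i]} vs {labels[j]}")
            raws.append(r.p_value)
            results.append(r)
    adj = adjust_bonferroni(raws)
    return GroupComparison(
        marker,
        tuple(labels),
        means,
        "anova_bonferroni",
        tuple(adj),
        tuple(contrasts),
        (omnibus, *results),
    )
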