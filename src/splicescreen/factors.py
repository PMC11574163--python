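"""Splicing-factor correlation screen.

Within each cancer type, the planted event's PSI across *tumor* samples is
correlated (Pearson) against each factor's log2(FPKM + 1) expression;
factors are ranked by their median r across evaluable types, most negative
first.  A cross-cancer mode correlates per-type dPSI against per-type
d(mean log2 expression), one point per cancer type.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from splicescreen.stats import pearson
from splicescreen.types import CohortBundle, SpliceEvent, Tissue

__all__ = [
    "FactorCorrelation",
    "FactorRanking",
    "correlate_factor",
    "screen_factors",
    "cross_cancer_delta_correlation",
]


@dataclass(frozen=True)
class FactorCorrelation:
    factor: str
    cancer_type: str
    r: float  # NaN when unevaluated
    p_value: float
    n: int
    reason: str | None = None  # why unevaluated, when it is

    @property
    def evaluated(self) -> bool:
        return not math.isnan(self.r)


@dataclass(frozen=True)
class FactorRanking:
    factor: str
    r_by_type: dict  # cancer_type -> r (evaluated types only)
    summary_r: float  # median r across evaluated types
    n_types_negative: int  # types with r < negative_cut
    rank: int | None = None


def correlate_factor(
    psi_vector,
    expr_vector,
    factor: str = "",
    cancer_type: str = "",
    min_n: int = 10,
    log_transform: bool = True,
) -> FactorCorrelation:
    """Pearson correlation of event PSI vs factor expression over paired
    samples, with pairwise-complete deletion of missing entries and a
    log2(FPKM + 1) transform of expression (configurable off)."""
    x = np.asarray(psi_vector, dtype=float)
    y = np.asarray(expr_vector, dtype=float)
    if x.shape != y.shape:
        raise ValueError("psi and expression vectors must align")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if log_transform:
        y = np.log2(y + 1.0)
    n = len(x)
    if n < min_n:
        return FactorCorrelation(
            factor, cancer_type, math.nan, math.nan, n, reason="too few samples"
        )
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return FactorCorrelation(
            factor, cancer_type, math.nan, math.nan, n, reason="constant series"
        )
    res = pearson(x, y)
    return FactorCorrelation(factor, cancer_type, res.statistic, res.p_value, n)


def screen_factors(
    bundles: list[CohortBundle],
    event: SpliceEvent | str,
    factor_list: list[str],
    min_n: int = 10,
    log_transform: bool = True,
    negative_cut: float = -0.3,
) -> list[FactorRanking]:
    """Rank every factor by the median of its per-type tumor-sample r,
    ascending (most negative coupling first); ties broken by symbol."""
    if not factor_list:
        raise ValueError("factor list is empty")
    event_id = event if isinstance(event, str) else event.event_id

    per_factor: dict[str, dict[str, float]] = {f: {} for f in factor_list}
    for b in bundles:
        if event_id not in b.psi:
            continue
        tumor_ids = [s.sample_id for s in b.samples_by_tissue(Tissue.TUMOR)]
        psi_row = b.psi.row(event_id)
        psi_vec = psi_row.reindex(tumor_ids).to_numpy(dtype=float)
        for f in factor_list:
            if f not in b.expr:
                continue
            expr_vec = b.expr.row(f).reindex(tumor_ids).to_numpy(dtype=float)
            fc = correlate_factor(
                psi_vec, expr_vec, f, b.cancer_type, min_n, log_transform
            )
            if fc.evaluated:
                per_factor[f][b.cancer_type] = fc.r

    if not any(per_factor.values()):
        raise ValueError("no factor evaluable in any cancer type")

    rankings = []
    for f in factor_list:
        rs = per_factor[f]
        if rs:
            summary = float(np.median(list(rs.values())))
            n_neg = sum(r < negative_cut for r in rs.values())
        else:
            summary, n_neg = math.nan, 0
        rankings.append(FactorRanking(f, dict(rs), summary, n_neg))
    # unevaluated factors (NaN summary) sort last
    rankings.sort(
        key=lambda r: (math.isnan(r.summary_r), r.summary_r if not math.isnan(r.summary_r) else 0.0, r.factor)
    )
    return [
        FactorRanking(r.factor, r.r_by_type, r.summary_r, r.n_types_negative, i + 1)
        for i, r in enumerate(rankings)
    ]


def cross_cancer_delta_correlation(
    dpsi_by_type: dict, dexpr_by_type: dict
) -> tuple[float, float, int]:
    """Pearson correlation across cancer types of event dPSI against the
    factor's d(mean log2(FPKM+1)) — one point per type with both deltas.

    Returns (r, p, n_types); (NaN, NaN, n) when fewer than 3 points.
    """
    common = sorted(set(dpsi_by_type) & set(dexpr_by_type))
    xs = np.array([dpsi_by_type[t] for t in common], dtype=float)
    ys = np.array([dexpr_by_type[t] for t in common], dtype=float)
    keep = ~(np.isnan(xs) | np.isnan(ys))
    xs, ys = xs[keep], ys[keep]
    n = len(xs)
    if n < 3:
        return math.nan, math.nan, n
    res = pearson(xs, ys)
    return res.statistic, res.p_value, n


def factor_delta_expression(
    bundle: CohortBundle, factor: str
) -> float:
    """Tumor-minus-normal difference of mean log2(FPKM+1) for one factor."""
    row = bundle.expr.row(factor)
    out = {}
    for tissue in (Tissue.TUMOR, Tissue.NORMAL):
        ids = [s.sample_id for s in bundle.samples_by_tissue(tissue)]
        vals = row.reindex(ids).to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        out[tissue] = float(np.mean(np.log2(vals + 1.0))) if len(vals) else math.nan
    return out[Tissue.TUMOR] - out[Tissue.NORMAL]
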