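"""Per-cancer event summaries, cross-cancer detection filters, and the
mean |dPSI| ranking.

Conventions: dPSI = mean tumor PSI - mean normal PSI (positive = more
inclusion in cancer).  An event is *quantified* in a cancer type when both
tissue groups have at least ``min_n`` non-missing samples, and *detected*
when it is quantified and either its two-tailed pooled-variance t-test is
below alpha or |dPSI| exceeds a small floor.  The pan-cancer score is the
mean of |dPSI| over quantified types only (no zero-imputation).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from splicescreen.stats import student_t_two_sample
from splicescreen.types import PsiMatrix, SampleRecord, SpliceEvent, Tissue

logger = logging.getLogger(__name__)

__all__ = [
    "EventSummary",
    "PanCancerRank",
    "summarize_event",
    "summarize_bundle",
    "filter_events",
    "rank_events",
]


@dataclass(frozen=True)
class EventSummary:
    event: SpliceEvent
    cancer_type: str
    n_tumor: int
    n_normal: int
    quantified: bool
    mean_psi_tumor: float = math.nan
    mean_psi_normal: float = math.nan
    delta_psi: float = math.nan
    t_stat: float = math.nan
    p_value: float = math.nan

    def detected(self, alpha: float = 0.05, dpsi_floor: float = 0.01) -> bool:
        if not self.quantified:
            return False
        return (not math.isnan(self.p_value) and self.p_value < alpha) or abs(
            self.delta_psi
        ) > dpsi_floor


@dataclass(frozen=True)
class PanCancerRank:
    event: SpliceEvent
    delta_by_type: dict  # cancer_type -> dPSI (absent where unquantified)
    n_types_quantified: int
    n_types_detected: int
    mean_abs_dpsi: float
    rank: int | None = None


def summarize_event(
    psi: PsiMatrix,
    samples: list[SampleRecord],
    event: SpliceEvent | str,
    cancer_type: str | None = None,
    min_n: int = 10,
) -> EventSummary:
    """Tumor-vs-normal summary of one event in one cancer type."""
    event_id = event if isinstance(event, str) else event.event_id
    row = psi.row(event_id)  # raises KeyError if absent
    ev = psi.event(event_id)
    if cancer_type is None:
        cancer_type = samples[0].cancer_type if samples else ""

    groups = {Tissue.TUMOR: [], Tissue.NORMAL: []}
    for s in samples:
        if s.sample_id in row.index:
            v = row[s.sample_id]
            if not np.isnan(v):
                groups[s.tissue].append(float(v))
    tum = np.asarray(groups[Tissue.TUMOR])
    nor = np.asarray(groups[Tissue.NORMAL])
    n_t, n_n = len(tum), len(nor)
    if n_t < min_n or n_n < min_n:
        return EventSummary(ev, cancer_type, n_t, n_n, quantified=False)

    mt, mn = float(tum.mean()), float(nor.mean())
    delta = mt - mn
    try:
        res = student_t_two_sample(tum, nor, pooled=True)
        t, p = res.statistic, res.p_value
    except ValueError:  # both groups constant
        t, p = (0.0, 1.0) if delta == 0 else (math.inf, 0.0)
    return EventSummary(
        ev, cancer_type, n_t, n_n, True, mt, mn, delta, t, p
    )


def summarize_bundle(
    bundle, events: list[SpliceEvent] | None = None, min_n: int = 10
) -> list[EventSummary]:
    """Summaries for all (or the given) events of one cohort bundle."""
    evs = events if events is not None else bundle.psi.events
    return [
        summarize_event(bundle.psi, bundle.samples, e, bundle.cancer_type, min_n)
        for e in evs
    ]


def _group_by_event(
    summaries: list[EventSummary],
) -> dict[str, list[EventSummary]]:
    by_event: dict[str, list[EventSummary]] = {}
    for s in summaries:
        by_event.setdefault(s.event.event_id, []).append(s)
    return by_event


def filter_events(
    summaries: list[EventSummary],
    quantified_frac: float = 0.80,
    min_detected: int = 12,
    alpha: float = 0.05,
    dpsi_floor: float = 0.01,
) -> list[str]:
    """Retain events quantified in >= ``quantified_frac`` of the cancer types
    AND detected in >= ``min_detected`` of them.

    Both boundaries are inclusive ("at least").  The number of cancer types
    is taken from the summaries themselves (one summary per event per type).
    """
    if not 0.0 < quantified_frac <= 1.0:
        raise ValueError(f"quantified_frac must be in (0, 1], got {quantified_frac}")
    by_event = _group_by_event(summaries)
    retained = []
    for event_id, ss in sorted(by_event.items()):
        n_types = len(ss)
        n_quant = sum(s.quantified for s in ss)
        n_det = sum(s.detected(alpha, dpsi_floor) for s in ss)
        if n_quant / n_types >= quantified_frac and n_det >= min_detected:
            retained.append(event_id)
    return retained


def rank_events(
    summaries: list[EventSummary],
    retained: list[str] | None = None,
    alpha: float = 0.05,
    dpsi_floor: float = 0.01,
) -> list[PanCancerRank]:
    """Rank events by mean |dPSI| over quantified types, descending; ties
    broken by event id ascending."""
    by_event = _group_by_event(summaries)
    if retained is not None:
        by_event = {k: v for k, v in by_event.items() if k in set(retained)}
    if not by_event:
        logger.warning("no events to rank; returning empty ranking")
        return []
    ranks = []
    for event_id, ss in by_event.items():
        deltas = {s.cancer_type: s.delta_psi for s in ss if s.quantified}
        n_quant = len(deltas)
        mean_abs = (
            float(np.mean([abs(d) for d in deltas.values()])) if n_quant else 0.0
        )
        ranks.append(
            PanCancerRank(
                event=ss[0].event,
                delta_by_type=deltas,
                n_types_quantified=n_quant,
                n_types_detected=sum(s.detected(alpha, dpsi_floor) for s in ss),
                mean_abs_dpsi=mean_abs,
            )
        )
    ranks.sort(key=lambda r: (-r.mean_abs_dpsi, r.event.event_id))
    return [
        PanCancerRank(
            r.event,
            r.delta_by_type,
            r.n_types_quantified,
            r.n_types_detected,
            r.mean_abs_dpsi,
            rank=i + 1,
        )
        for i, r in enumerate(ranks)
    ]
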